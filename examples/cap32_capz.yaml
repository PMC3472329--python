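# Comparison of the Dictyostelium cytoplasmic capping protein (Cap32/34,
# PDB 4AKR) against chicken sarcomeric CapZ (PDB 1IZN).
#
# Download the two deposited coordinate files yourself (they are not shipped)
# and adjust the paths and chain ids below: the chain naming of the two
# heterodimer copies in the deposited files is taken from this config, never
# assumed.  All residue ranges are author numbering, inclusive.
#
# Run:  cpcompare compare examples/cap32_capz.yaml --out cap32_vs_capz

structure_a: 4akr.pdb          # cytoplasmic Cap32/34 (alpha = Cap34, beta = Cap32)
structure_b: 1izn.pdb          # sarcomeric CapZ (alpha1/beta1)

# chain of structure_a -> chain of structure_b; one pairing per subunit.
# 4AKR contains two heterodimer copies; compare the first copy here and swap
# in the second copy's chain ids to reproduce the AU-copy superposition.
pairings:
  - [A, A]                     # alpha subunits
  - [B, B]                     # beta subunits

# stated exclusions from every fit: the flexible beta-subunit C-terminus
# (beta-tentacle) region; unmodeled residues drop out automatically.
fit_exclude_a:
  B: [[251, 272]]

# named regions reported in the global-fit frame with mean B on both sides
regions:
  flex_101_117:                # putative Z-disc interaction site of CapZ
    chain_a: A
    chain_b: A
    range_a: [101, 117]

# disorder reports: expected full sequence spans per chain
expected_ranges:
  - {structure: a, chain: A, range: [1, 281]}
  - {structure: a, chain: B, range: [1, 272]}

b_mode: ca                     # "ca" or "all" for B-factor statistics
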