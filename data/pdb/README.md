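# Crystal-structure inputs (user-supplied)

The lysozyme reproductions operate on three crystal structures that are not
distributed with this package and are never fetched automatically:

| file        | PDB ID | content                       |
|-------------|--------|-------------------------------|
| `1rex.pdb`  | 1REX   | wild-type human lysozyme      |
| `1loz.pdb`  | 1LOZ   | I56T amyloidogenic variant    |
| `1lyy.pdb`  | 1LYY   | D67H amyloidogenic variant    |

Download the PDB-format coordinate files from the Protein Data Bank
(https://www.rcsb.org), save them here under the lower-case names above, and
re-run the test suite and `scripts/acceptance.py`: the crystal-structure
checks (shared displaced residues 21/62/104/122, the 112–117 cluster scores,
the four-retained-clusters count) activate automatically.  Docked dimer or
trimer complexes from any docking program can be analyzed with
`rincompare interface <complex.pdb>`.
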