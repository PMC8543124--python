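# Reference structures

Deposited PDB coordinates are not redistributed with the package.  Place
entries here as `<id>.pdb` and `aanet.datasets.resolve_structure` will find
them; otherwise it attempts an RCSB download.

The case study is the third PDZ domain of PSD-95 with its bound peptide
ligand:

    curl -o data/1be9.pdb https://files.rcsb.org/download/1BE9.pdb
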