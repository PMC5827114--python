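# data/

Place a local copy of the deposited crystal structure of the Syncrip
two-domain construct here to enable the real-structure interface-burial
analysis:

    data/6ES4.pdb    (or 6ES4.cif)

e.g. from https://www.rcsb.org/structure/6ES4 (`curl -O
https://files.rcsb.org/download/6ES4.pdb`). The coordinates are not
redistributed with this repository. When the file is absent, the
structural stages and tests that depend on it report it as missing; all
synthetic-data analyses run regardless.
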