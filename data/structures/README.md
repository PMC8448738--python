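# Deposited coordinate files

Place downloaded mmCIF files of the cyanobacterial phycobilisome
depositions here to enable the published-structure reproduction tests:

    curl -O https://files.rcsb.org/download/7EXT.cif   # Synechococcus 7002 PBS
    curl -O https://files.rcsb.org/download/7EYD.cif   # Anabaena 7120 PBS

Nothing in this directory is required for the rest of the test suite or
for `scripts/acceptance.py`, which run entirely on generated synthetic
assemblies. Files in this directory are never downloaded automatically.
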