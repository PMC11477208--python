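# Reference structures

The crystallographic calibration (tests/test_acceptance.py::TestXrayCalibration)
reads two public PDB entries from this directory:

- `5N69.pdb` — bovine beta-cardiac myosin motor domain + essential light chain
  with omecamtiv mecarbil bound (chains A and H are used)
- `8EFE.pdb` — post-powerstroke actomyosin complex (supplies the actin
  pentamer and the helix-loop-helix alignment target)

They are distributed by the Protein Data Bank and are not bundled here.
Download them, e.g.:

    curl -O https://files.rcsb.org/download/5N69.pdb
    curl -O https://files.rcsb.org/download/8EFE.pdb
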