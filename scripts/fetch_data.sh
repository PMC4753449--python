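#!/bin/sh
# Download the deposited structures and experimental scattering curve used
# by the accession-based validation tests (tests/test_acceptance.py) and
# by analysis/05_accession_validation.py.  Requires network access.
set -eu
mkdir -p data
curl -fsSL -o data/3DKX.pdb https://files.rcsb.org/download/3DKX.pdb
curl -fsSL -o data/3DKY.pdb https://files.rcsb.org/download/3DKY.pdb
# SASBDB experimental curve for the hexamer in solution
curl -fsSL -o data/SASDBC3.dat \
  "https://www.sasbdb.org/media/intensities_files/SASDBC3.dat"
echo "fetched: $(ls data)"
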