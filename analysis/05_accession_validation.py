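#!/usr/bin/env python
"""Validation against the deposited structures and experimental curve.

Requires data/3DKX.pdb, data/3DKY.pdb and data/SASDBC3.dat (see
scripts/fetch_data.sh).  Reproduces: the nine C6-symmetrised models and
their clash ranking; the Cα RMSDs of the C2/C3/C6B transitions; the
mode-transition overlap table across an ANM-cutoff scan; and the
experimental Guinier Rg, Dmax and per-model χ ordering.
"""

from __future__ import annotations

from pathlib import Path
import sys

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import ringflex as rf

ROOT = Path(__file__).resolve().parent.parent
DATA, OUT = ROOT / "data", ROOT / "results"


def hexamer(path: Path) -> rf.StructureModel:
    model = rf.read_structure(path)
    if len(model.protomers) < 6:
        model = rf.read_structure(path, expand_assembly=True)
    return model


def main() -> int:
    needed = [DATA / n for n in ("3DKX.pdb", "3DKY.pdb", "SASDBC3.dat")]
    missing = [p.name for p in needed if not p.exists()]
    if missing:
        print(f"missing {missing}; run scripts/fetch_data.sh first")
        return 1
    OUT.mkdir(exist_ok=True)

    c2_au, c3_au = rf.read_structure(needed[0]), rf.read_structure(needed[1])
    hex_c2, hex_c3 = hexamer(needed[0]), hexamer(needed[1])

    models = rf.enumerate_symmetrized_models(
        [c2_au, c3_au], od_range=(135, 204), n=6, template=hex_c3
    )
    print("symmetrised-model clash ranking:")
    for i, m in enumerate(models):
        print(f"  {i + 1}. {m.label}: {m.clash_count} contacts < 3.5 Å")

    c6b = rf.build_symmetrized_model(
        c2_au, "B", od_range=(135, 204), template=hex_c3
    )
    rf.write_structure(c6b.model, OUT / "C6B.pdb")

    ca = {
        "C2": rf.select_calpha(hex_c2, (4, 204)),
        "C3": rf.select_calpha(hex_c3, (4, 204)),
        "C6B": rf.select_calpha(c6b.model, (4, 204)),
    }
    print("\ntransition Cα RMSDs (ring-aware / fixed pairing):")
    for a, b in (("C2", "C6B"), ("C2", "C3"), ("C3", "C6B")):
        sym = rf.symmetry_rmsd(ca[a], ca[b], 6)
        _, plain = rf.superpose(ca[b], ca[a])
        print(f"  {a}-{b}: {sym:.2f} / {plain:.2f} Å")

    for cutoff in (10.0, 12.0, 13.0, 15.0, 18.0):
        cfg = rf.AnalysisConfig(anm_cutoff=cutoff, n_random=10_000, seed=1,
                                outdir=str(OUT / f"overlap_rc{cutoff:.0f}"))
        overlaps, tt = rf.run_transition_report(ca, cfg)
        o = overlaps.set_index(["modes_of", "target"])
        print(
            f"\ncutoff {cutoff:.0f} Å: dot2(C2 modes, T_C2->C6B) = "
            f"{o.loc[('C2', 'C6B'), 'dot2']:.2f}; "
            f"dot2(C6B modes, T_C6B->C2) = {o.loc[('C6B', 'C2'), 'dot2']:.2f}"
        )

    curve = rf.read_sas_curve(needed[2], unit="nm^-1")
    rg, _, _ = rf.guinier_fit(curve)
    dd = rf.ift_estimate(curve, dmax_scan=np.arange(80, 141, 2.5))
    print(f"\nexperimental curve: Guinier Rg = {rg:.1f} Å, IFT Dmax = {dd.dmax:.0f} Å")

    rep = rf.run_saxs_report(curve, ca, rf.AnalysisConfig(seed=1, outdir=str(OUT)))
    print("\nper-model χ against the experimental curve:")
    print(rep["per_model"].round(3).to_string(index=False))
    mix = rep["mixture"]
    frac = ", ".join(f"{i}: {w:.2f}" for i, w in zip(mix.basis_ids, mix.weights))
    print(f"mixture: chi = {mix.chi:.2f} ({frac})")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
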