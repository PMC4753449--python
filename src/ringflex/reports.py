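"""Orchestration of the two analysis arms: mode/transition overlap tables
and SAXS model/mixture/ensemble fitting, as reproducible report objects.

Every report is a plain pandas DataFrame (written as TSV when an output
directory is configured) and embeds the conventions used — residue ranges,
ANM cutoff, χ definition, seeds — so a rerun with the same config
reproduces every number exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enm import anm_modes
from .errors import DegenerateTransitionError
from .geometry import superpose, symmetry_rmsd
from .saxs import (
    GASettings,
    MixtureFit,
    ScatteringProfile,
    chi_discrepancy,
    debye_profile,
    fit_mixture,
    select_ensemble_ga,
)
from .structures import CoordinateSet
from .transitions import (
    overlap_zscore,
    transition_dot,
    transition_vector,
    transition_vector_in_frame,
)

__all__ = ["AnalysisConfig", "run_transition_report", "run_saxs_report"]


@dataclass
class AnalysisConfig:
    """Conventions shared by all reports.

    Residue-range defaults follow the two-domain architecture of the
    initiator protomer: outer (origin-binding) domain 4–129, hinge 128–134,
    inner (oligomerisation) domain 135–204; Cα selection 4–204.
    """

    calpha_range: tuple[int, int] = (4, 204)
    obd_range: tuple[int, int] = (4, 129)
    hinge_range: tuple[int, int] = (128, 134)
    od_range: tuple[int, int] = (135, 204)
    anm_cutoff: float = 13.0
    n_modes: int = 20
    j_list: tuple[int, ...] = (2, 5, 10)
    n_random: int = 10_000
    seed: int = 0
    s_unit: str = "A^-1"
    ga: GASettings = field(default_factory=GASettings)
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def _write(self, df: pd.DataFrame, name: str) -> None:
        if self.outdir:
            out = Path(self.outdir)
            out.mkdir(parents=True, exist_ok=True)
            df.to_csv(out / name, sep="\t", index=False)


def run_transition_report(
    conformers: dict[str, CoordinateSet],
    config: AnalysisConfig | None = None,
    ring_order: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full overlap matrix between conformer transitions and ANM modes.

    For every ordered pair (source, target): modes are computed on the
    source structure restricted to the pairwise label intersection, the
    transition vector source→target is projected on them, and the
    cumulative overlaps are reported with their chance level j/dof and a
    seeded Monte-Carlo Z-score.  A second table gives pairwise RMSDs and
    the dot products between transitions sharing a conformer.

    Pairs that coincide after superposition produce a diagnostic row with
    NaN overlaps rather than an error.
    """
    cfg = config or AnalysisConfig()
    names = list(conformers)
    rows = []
    for src, dst in itertools.permutations(names, 2):
        a, b = conformers[src], conformers[dst]
        common = a.common_labels(b)
        a_sub, b_sub = a.subset(common), b.subset(common)
        _, rmsd = superpose(b_sub, a_sub)
        row: dict = {
            "modes_of": src,
            "target": dst,
            "n_beads": len(common),
            "rmsd": rmsd,
        }
        if ring_order is not None:
            try:
                row["sym_rmsd"] = symmetry_rmsd(a_sub, b_sub, ring_order)
            except ValueError:
                row["sym_rmsd"] = np.nan
        try:
            T = transition_vector(a_sub, b_sub, src, dst)
        except DegenerateTransitionError:
            for j in cfg.j_list:
                row[f"dot{j}"] = np.nan
            row["degenerate"] = True
            rows.append(row)
            continue
        modes = anm_modes(a_sub, n_modes=max(cfg.j_list), cutoff=cfg.anm_cutoff)
        for j in cfg.j_list:
            res = overlap_zscore(modes, T, j, n_random=cfg.n_random, seed=cfg.seed)
            row[f"dot{j}"] = res.dot_j
            row[f"chance{j}"] = res.chance
            row[f"z{j}"] = res.zscore
        row["degenerate"] = False
        rows.append(row)
    overlaps = pd.DataFrame(rows)
    overlaps.attrs["config_hash"] = cfg.config_hash()

    # transition-transition dot products for transitions sharing a conformer,
    # both expressed in the shared conformer's frame
    tt_rows = []
    for x, shared, y in itertools.permutations(names, 3):
        # triple label intersection so both vectors share labels and frame
        labels = [
            lab
            for lab in conformers[x].common_labels(conformers[shared])
            if lab in set(conformers[y].labels)
        ]
        if len(labels) < 3:
            continue
        cx = conformers[x].subset(labels)
        cs = conformers[shared].subset(labels)
        cy = conformers[y].subset(labels)
        try:
            t1 = transition_vector_in_frame(cx, cs, cs, x, shared, shared)
            t2 = transition_vector_in_frame(cs, cy, cs, shared, y, shared)
        except DegenerateTransitionError:
            continue
        tt_rows.append(
            {
                "t1": f"{x}->{shared}",
                "t2": f"{shared}->{y}",
                "frame": shared,
                "dot": transition_dot(t1, t2),
            }
        )
    tt = pd.DataFrame(tt_rows)
    cfg._write(overlaps, "transition_overlaps.tsv")
    cfg._write(tt, "transition_dots.tsv")
    return overlaps, tt


def run_saxs_report(
    exp: ScatteringProfile,
    models: dict[str, CoordinateSet],
    config: AnalysisConfig | None = None,
    pool: list[ScatteringProfile] | None = None,
    ensemble_size: int = 12,
) -> dict:
    """Per-model χ, best mixture, and (optionally) GA ensemble selection.

    Model profiles are Debye curves on the experimental s grid; the
    mixture fit assigns non-negative sum-to-one volume fractions; when a
    conformer pool is supplied the GA selects a fixed-size sub-ensemble
    and its members are post-processed with the mixture fitter to attach
    fractions.
    """
    cfg = config or AnalysisConfig()
    if exp.sigma is None:
        raise ValueError("experimental curve must carry errors")
    names = list(models)
    profiles = {
        name: debye_profile(models[name], exp.s, unit=exp.unit) for name in names
    }
    per_model = []
    for name in names:
        chi, scale = chi_discrepancy(exp, profiles[name])
        per_model.append({"model": name, "chi": chi, "scale": scale})
    per_model_df = pd.DataFrame(per_model).sort_values("chi", ignore_index=True)

    mixture: MixtureFit = fit_mixture(exp, [profiles[n] for n in names], names)
    result: dict = {
        "per_model": per_model_df,
        "mixture": mixture,
        "config_hash": cfg.config_hash(),
    }

    if pool is not None:
        sel = select_ensemble_ga(
            exp, pool, ensemble_size, settings=cfg.ga, seed=cfg.seed
        )
        unique = sorted(set(sel.members))
        post = fit_mixture(exp, [pool[i] for i in unique], [str(i) for i in unique])
        result["ensemble"] = sel
        result["ensemble_fractions"] = post

    cfg._write(per_model_df, "saxs_per_model.tsv")
    cfg._write(
        pd.DataFrame(
            {"model": mixture.basis_ids, "fraction": mixture.weights}
        ).assign(chi=mixture.chi),
        "saxs_mixture.tsv",
    )
    return result
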