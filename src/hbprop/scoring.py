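"""Binding-site selection and ligand ranking from bond propensities.

Workflow: chameleonic bonds are identified on the apo protein, restricted
to the binding interface (any bond whose donor N or acceptor O lies within
6 Angstrom of a heavy atom of the binding partner in the complex), and
their complex-state fraction-broken values — averaged over simulation
replicas — are condensed into a single per-ligand score DM, the mean D
over the chameleonic set.  Lower DM means stronger quenching of the
labile bonds and predicts higher affinity; DM correlates with log IC50
across ligand series.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hbond import BondKey, PropensityMatrix
from .structure import AtomRecord, BackboneStructure

__all__ = [
    "SiteCriterion",
    "ReplicaSet",
    "AffinityRecord",
    "DMScore",
    "select_binding_site",
    "fraction_broken",
    "replica_average",
    "relative_labilization",
    "dm_score",
    "correlate_affinity",
    "read_affinity_csv",
    "write_score_report",
]


@dataclass(frozen=True)
class SiteCriterion:
    """Interface rule: bond probe atoms within ``cutoff`` of the partner.

    The probe atoms of a backbone bond are its donor amide N and its
    acceptor carbonyl O; the partner pool is every heavy atom of the
    binding partner in the complex structure.  Default cutoff 6 Angstrom,
    strict.
    """

    cutoff: float = 6.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class ReplicaSet:
    """Per-replica propensity matrices over one common bond set."""

    replicas: list[PropensityMatrix]

    def __post_init__(self):
        if not self.replicas:
            raise ValueError("need at least one replica")
        keys = set(self.replicas[0].entries)
        for rep in self.replicas[1:]:
            if set(rep.entries) != keys:
                raise ValueError("replicas cover different bond sets")

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def fraction_broken_stats(self) -> dict[BondKey, tuple[float, float]]:
        """Replica mean and sample SD of 1 - propensity, per bond."""
        out = {}
        for key in self.replicas[0].entries:
            vals = [fraction_broken(rep.entries[key]) for rep in self.replicas]
            out[key] = replica_average(vals)
        return out


@dataclass(frozen=True)
class AffinityRecord:
    """Experimental potency of one molecule (IC50 in nM)."""

    molecule: str
    ic50: float

    def __post_init__(self):
        if not (math.isfinite(self.ic50) and self.ic50 > 0):
            raise ValueError(f"IC50 must be finite and positive: {self.ic50}")


@dataclass
class DMScore:
    """Per-molecule mean D over the chameleonic bond set."""

    molecule: str
    per_bond_D: dict[BondKey, float]
    dm: float


def select_binding_site(protein: BackboneStructure,
                        partner_heavy_atoms: list[AtomRecord],
                        bonds: list[BondKey],
                        site: SiteCriterion = SiteCriterion()
                        ) -> list[BondKey]:
    """Keep bonds whose N or O sits within ``site.cutoff`` of the partner.

    The minimum distance from the donor amide N or the acceptor carbonyl O
    to any partner heavy atom must be strictly below the cutoff.  Order of
    the input list is preserved.
    """
    if not partner_heavy_atoms:
        raise ValueError("partner heavy-atom pool is empty")
    pool = np.array([a.xyz for a in partner_heavy_atoms])
    kept = []
    for key in bonds:
        n = protein.residue(key.donor).coord("N")
        o = protein.residue(key.acceptor).coord("O")
        dmin = min(np.linalg.norm(pool - n, axis=1).min(),
                   np.linalg.norm(pool - o, axis=1).min())
        if dmin < site.cutoff:
            kept.append(key)
    return kept


def fraction_broken(propensity: float) -> float:
    """1 - formation propensity.

    For a complex whose bonds are all formed in the PDB (state value 1)
    this equals D, the fraction of simulation time the bond is broken.
    """
    if not (0.0 <= propensity <= 1.0):
        raise ValueError(f"propensity outside [0,1]: {propensity}")
    return 1.0 - propensity


def replica_average(values: list[float]) -> tuple[float, float]:
    """Unweighted mean and sample SD over replicas (SD = 0 for n = 1)."""
    if not values:
        raise ValueError("cannot average zero replicas")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def relative_labilization(d_reference: float, d_variant: float) -> float:
    """Percent change of fraction-broken relative to a reference.

    Used for alanine-scanning reports: a mutation that doubles a bond's
    breakage tendency scores +100 %.
    """
    if d_reference == 0:
        raise ValueError("relative change undefined for zero reference")
    if d_reference < 0:
        raise ValueError("reference fraction-broken must be positive")
    return 100.0 * (d_variant - d_reference) / d_reference


def dm_score(per_bond_D: dict[BondKey, float],
             molecule: str = "") -> DMScore:
    """Arithmetic mean of D over the chameleonic bond set."""
    if not per_bond_D:
        raise ValueError("DM undefined for an empty bond set")
    dm = float(np.mean(list(per_bond_D.values())))
    return DMScore(molecule=molecule, per_bond_D=dict(per_bond_D), dm=dm)


def correlate_affinity(scores: list[DMScore],
                       affinities: list[AffinityRecord],
                       scale: str = "log10"
                       ) -> tuple[float, float, float]:
    """Pearson correlation and least-squares line of DM vs affinity.

    Molecules are matched by label.  ``scale="log10"`` regresses DM on
    log10(IC50) (the natural choice when potencies span orders of
    magnitude); ``"linear"`` uses IC50 directly.  Returns
    (pearson_r, slope, intercept) of DM = slope * x + intercept.
    """
    if scale not in ("log10", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    aff = {a.molecule: a.ic50 for a in affinities}
    missing = [s.molecule for s in scores if s.molecule not in aff]
    if missing:
        raise ValueError(f"no affinity for molecules: {missing}")
    if len(scores) < 3:
        raise ValueError("need at least 3 matched molecules to correlate")
    x = np.array([aff[s.molecule] for s in scores], dtype=float)
    if scale == "log10":
        x = np.log10(x)
    y = np.array([s.dm for s in scores], dtype=float)
    fit = stats.linregress(x, y)
    return float(fit.rvalue), float(fit.slope), float(fit.intercept)


# ---------------------------------------------------------------------------
# I/O helpers


def read_affinity_csv(path) -> list[AffinityRecord]:
    """Read a molecule,ic50_nM table."""
    frame = pd.read_csv(path, comment="#")
    cols = {c.strip().lower() for c in frame.columns}
    if not {"molecule", "ic50_nm"} <= cols:
        raise ValueError("affinity CSV needs columns molecule,ic50_nM")
    frame.columns = [c.strip().lower() for c in frame.columns]
    return [AffinityRecord(str(row.molecule), float(row.ic50_nm))
            for row in frame.itertuples()]


def write_score_report(path_csv, path_json, molecule: str,
                       replicas: ReplicaSet,
                       exclude: list[BondKey] = ()) -> DMScore:
    """Write the per-bond / per-replica report and return the DM score.

    ``exclude`` drops bonds explicitly (e.g. bonds lost to construct
    truncation); exclusion is always recorded in the output, never silent.
    """
    stats_map = replicas.fraction_broken_stats()
    scored = {k: mean for k, (mean, _) in stats_map.items()
              if k not in set(exclude)}
    score = dm_score(scored, molecule=molecule)
    rows = []
    for key, (mean, sd) in sorted(stats_map.items(),
                                  key=lambda kv: kv[0].donor):
        row = {"bond": key.label}
        for i, rep in enumerate(replicas.replicas, start=1):
            row[f"D_rep{i}"] = round(fraction_broken(rep.entries[key]), 4)
        row["D_mean"] = round(mean, 4)
        row["D_sd"] = round(sd, 4)
        row["excluded"] = key in set(exclude)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path_csv, index=False)
    summary = {
        "molecule": molecule,
        "dm": score.dm,
        "n_replicas": replicas.n_replicas,
        "bonds": {k.label: v for k, v in scored.items()},
        "excluded_bonds": [k.label for k in exclude],
    }
    with open(path_json, "w") as fh:
        json.dump(summary, fh, indent=2)
    return score
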