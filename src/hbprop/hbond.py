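"""Backbone hydrogen-bond propensity analysis.

The central objects are two contact matrices over backbone hydrogen bonds
(BHBs, amide N-H of a donor residue to the carbonyl O of an acceptor):

* the *static* matrix, evaluated once on a PDB structure, with entries in
  {0, 1} (bond formed / not formed in the deposited coordinates), and
* the *dynamic* (time-averaged) matrix, the fraction of trajectory frames
  in which the geometric criterion is satisfied.

Their per-bond difference D = static_state - propensity exposes
"chameleonic" bonds: interactions whose solution-phase behaviour
contradicts their crystallographic state (|D| > 0.5 by default).  For a
complex in which every bond is formed in the PDB, D is simply the fraction
of time the bond is broken.

Geometric criterion defaults: N-O distance r < 3.5 Angstrom and N-H-O
angle (vertex at H) theta > 140 degrees, both strict.  A distance-only
mode is provided for per-frame N-O distance tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import BackboneStructure, ResidueRef, StructureError

__all__ = [
    "HBCriterion",
    "BondKey",
    "StaticContactMatrix",
    "PropensityMatrix",
    "DeltaMatrix",
    "ChameleonReport",
    "TrajectoryFrames",
    "DistanceSeries",
    "hb_geometry",
    "is_formed",
    "enumerate_candidate_bonds",
    "static_contact_matrix",
    "dynamic_propensity",
    "propensity_from_distance_series",
    "delta_matrix",
    "classify_chameleonic",
    "windowed_propensity",
]

#: decimals used when reporting propensities and D values
REPORT_DECIMALS = 4


@dataclass(frozen=True)
class HBCriterion:
    """Geometric hydrogen-bond formation criterion.

    ``full`` mode requires r < r_max AND theta > theta_min (both strict);
    ``distance_only`` ignores the angle, for use with N-O distance tables.
    """

    r_max: float = 3.5
    theta_min: float = 140.0
    mode: str = "full"

    def __post_init__(self):
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if not (0.0 < self.theta_min <= 180.0):
            raise ValueError("theta_min must lie in (0, 180]")
        if self.mode not in ("full", "distance_only"):
            raise ValueError(f"unknown criterion mode {self.mode!r}")


@dataclass(frozen=True)
class BondKey:
    """Directional bond identity: donor N-H -> acceptor C=O."""

    donor: ResidueRef
    acceptor: ResidueRef

    def __post_init__(self):
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor must differ")

    @classmethod
    def from_seq(cls, donor_seq: int, acceptor_seq: int,
                 chain: str = "A") -> "BondKey":
        """Build a key from bare residue numbers (res_name left UNK)."""
        return cls(ResidueRef(chain, donor_seq), ResidueRef(chain, acceptor_seq))

    @property
    def label(self) -> str:
        return f"{self.donor.seq_number}-{self.acceptor.seq_number}"

    def __str__(self) -> str:
        return f"{self.donor} -> {self.acceptor}"


@dataclass
class StaticContactMatrix:
    """Binary BHB contact map of one static structure."""

    entries: dict[BondKey, int]
    criterion: HBCriterion
    source_label: str = ""

    def __post_init__(self):
        bad = {k: v for k, v in self.entries.items() if v not in (0, 1)}
        if bad:
            raise ValueError(f"static entries must be 0 or 1, got {bad}")


@dataclass
class PropensityMatrix:
    """Time-averaged BHB formation fractions over a trajectory."""

    entries: dict[BondKey, float]
    n_frames: int
    criterion: HBCriterion
    source_label: str = ""

    def __post_init__(self):
        for k, v in self.entries.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"propensity for {k} outside [0,1]: {v}")


@dataclass
class DeltaMatrix:
    """Per-bond D = static state - dynamic propensity, in [-1, 1]."""

    entries: dict[BondKey, float]
    static_source: str = ""
    dynamic_source: str = ""

    def __post_init__(self):
        for k, v in self.entries.items():
            if abs(v) > 1.0 + 1e-12:
                raise ValueError(f"|D| > 1 for {k}: {v}")


@dataclass
class ChameleonReport:
    """Bonds whose dynamics contradict their static state.

    ``chameleonic``: |D| > threshold (strict).  ``borderline``: |D| within
    [band_low, threshold] — close enough to the cutoff to deserve a look.
    Both lists are sorted by |D| descending.
    """

    chameleonic: list[tuple[BondKey, float]]
    borderline: list[tuple[BondKey, float]]
    threshold: float = 0.5
    band_low: float = 0.4


@dataclass
class TrajectoryFrames:
    """An ordered sequence of coordinate snapshots on a fixed topology."""

    frames: list[BackboneStructure]
    frame_stride_ps: float | None = None

    def __post_init__(self):
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class DistanceSeries:
    """Per-bond, per-frame N-O distances in Angstrom.

    The canonical file dialect is CSV with one column per bond, named
    ``"<donorSeq>-<acceptorSeq>"``, one row per frame, header required.
    The XLSX reader accepts the same layout in a spreadsheet.
    """

    data: pd.DataFrame
    source_label: str = ""

    def __post_init__(self):
        if self.data.shape[1] == 0:
            raise ValueError("distance series has no bond columns")
        if self.data.isna().any().any():
            raise ValueError("ragged or missing values in distance series")
        if (self.data.to_numpy() <= 0).any():
            raise ValueError("distances must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def bond_keys(self, chain: str = "A") -> list[BondKey]:
        keys = []
        for col in self.data.columns:
            d, a = str(col).split("-")
            keys.append(BondKey.from_seq(int(d), int(a), chain=chain))
        return keys

    @classmethod
    def from_mapping(cls, series: dict[str, list[float]],
                     source_label: str = "") -> "DistanceSeries":
        lengths = {len(v) for v in series.values()}
        if len(lengths) > 1:
            raise ValueError(f"ragged series lengths: {sorted(lengths)}")
        return cls(pd.DataFrame(series, dtype=float), source_label)

    @classmethod
    def from_csv(cls, path) -> "DistanceSeries":
        return cls(pd.read_csv(path, comment="#").astype(float),
                   source_label=str(path))

    @classmethod
    def from_xlsx(cls, path, sheet=0, skiprows=0) -> "DistanceSeries":
        frame = pd.read_excel(path, sheet_name=sheet, skiprows=skiprows)
        return cls(frame.astype(float), source_label=str(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# geometry


def hb_geometry(n_pos, h_pos, o_pos) -> tuple[float, float]:
    """Distance and angle of one N-H...O geometry.

    Returns ``(r, theta)`` where r = |N - O| in Angstrom and theta is the
    N-H-O angle in degrees with vertex at the hydrogen.
    """
    n = np.asarray(n_pos, dtype=float)
    h = np.asarray(h_pos, dtype=float)
    o = np.asarray(o_pos, dtype=float)
    if not (np.isfinite(n).all() and np.isfinite(h).all()
            and np.isfinite(o).all()):
        raise ValueError("non-finite coordinates")
    hn = n - h
    ho = o - h
    nhn = np.linalg.norm(hn)
    nho = np.linalg.norm(ho)
    if nhn < 1e-9 or nho < 1e-9:
        raise ValueError("coincident points in hydrogen-bond geometry")
    r = float(np.linalg.norm(n - o))
    cos_t = np.clip(np.dot(hn, ho) / (nhn * nho), -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cos_t)))
    return r, theta


def is_formed(r: float, theta: float | None,
              criterion: HBCriterion) -> bool:
    """Apply the formation criterion to one (r, theta) pair.

    Both cutoffs are strict: a frame sitting exactly on the boundary
    counts as broken.
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    if criterion.mode == "distance_only":
        return r < criterion.r_max
    if theta is None:
        raise ValueError("theta required for the full criterion")
    return (r < criterion.r_max) and (theta > criterion.theta_min)


# ---------------------------------------------------------------------------
# matrices


def enumerate_candidate_bonds(structure: BackboneStructure,
                              min_separation: int = 2) -> list[BondKey]:
    """All directional donor -> acceptor pairs worth evaluating.

    A residue qualifies as donor if it can carry an amide H (not proline,
    not chain-initial).  Pairs with |donor_seq - acceptor_seq| below
    ``min_separation`` are skipped to exclude trivially adjacent contacts.
    Order is deterministic: donor ascending, then acceptor ascending.
    """
    keys: list[BondKey] = []
    ordered = sorted(structure.residues, key=lambda r: r.ref)
    for don in ordered:
        if not don.donor_capable:
            continue
        for acc in ordered:
            if acc.ref == don.ref:
                continue
            if (don.ref.chain_id == acc.ref.chain_id and
                    abs(don.ref.seq_number - acc.ref.seq_number)
                    < min_separation):
                continue
            keys.append(BondKey(don.ref, acc.ref))
    return keys


def _bond_geometry(structure: BackboneStructure, key: BondKey,
                   criterion: HBCriterion) -> bool:
    don = structure.residue(key.donor)
    acc = structure.residue(key.acceptor)
    n = don.coord("N")
    o = acc.coord("O")
    if criterion.mode == "distance_only":
        return is_formed(float(np.linalg.norm(n - o)), None, criterion)
    if not don.has("H"):
        raise StructureError(
            f"donor {don.ref} has no amide H; run place_amide_hydrogens "
            "or use a distance_only criterion")
    r, theta = hb_geometry(n, don.coord("H"), o)
    return is_formed(r, theta, criterion)


def static_contact_matrix(structure: BackboneStructure,
                          criterion: HBCriterion = HBCriterion(),
                          min_separation: int = 2) -> StaticContactMatrix:
    """Binary contact matrix of one static structure."""
    entries = {}
    for key in enumerate_candidate_bonds(structure, min_separation):
        entries[key] = int(_bond_geometry(structure, key, criterion))
    return StaticContactMatrix(entries, criterion,
                               source_label=structure.source_label)


def dynamic_propensity(frames: TrajectoryFrames,
                       bonds: list[BondKey],
                       criterion: HBCriterion = HBCriterion()
                       ) -> PropensityMatrix:
    """Fraction of frames in which each bond satisfies the criterion.

    Frames are weighted equally; the result times n_frames is an integer
    count by construction.
    """
    counts = {key: 0 for key in bonds}
    for frame in frames.frames:
        for key in bonds:
            if _bond_geometry(frame, key, criterion):
                counts[key] += 1
    n = len(frames)
    return PropensityMatrix({k: c / n for k, c in counts.items()},
                            n_frames=n, criterion=criterion)


def propensity_from_distance_series(series: DistanceSeries,
                                    criterion: HBCriterion | None = None,
                                    chain: str = "A") -> PropensityMatrix:
    """Formation propensity from per-frame N-O distance tables.

    Uses the distance-only criterion (the angle is unavailable in a
    distance table); ``criterion.r_max`` defaults to 3.5 Angstrom.
    """
    if criterion is None:
        criterion = HBCriterion(mode="distance_only")
    if criterion.mode != "distance_only":
        raise ValueError("distance tables support only distance_only mode")
    entries = {}
    for key, col in zip(series.bond_keys(chain), series.data.columns):
        vals = series.data[col].to_numpy()
        entries[key] = float(np.count_nonzero(vals < criterion.r_max)
                             / len(vals))
    return PropensityMatrix(entries, n_frames=series.n_frames,
                            criterion=criterion,
                            source_label=series.source_label)


def delta_matrix(static: StaticContactMatrix,
                 dynamic: PropensityMatrix) -> DeltaMatrix:
    """D = static state - dynamic propensity, over the union of keys.

    A key absent from the static matrix has state 0 (the bond is not
    formed in the PDB); a key absent from the dynamic matrix has
    propensity 0 (never formed in the run).
    """
    keys = list(static.entries.keys())
    keys += [k for k in dynamic.entries if k not in static.entries]
    entries = {k: float(static.entries.get(k, 0))
               - dynamic.entries.get(k, 0.0) for k in keys}
    return DeltaMatrix(entries, static_source=static.source_label,
                       dynamic_source=dynamic.source_label)


def classify_chameleonic(delta: DeltaMatrix, threshold: float = 0.5,
                         band_low: float = 0.4) -> ChameleonReport:
    """Split bonds into chameleonic (|D| > threshold) and borderline.

    Chameleonic bonds contradict their PDB state in solution; borderline
    bonds (band_low <= |D| <= threshold) sit close enough to the cutoff
    that the caller may promote them by judgement, as is done for bonds a
    few hundredths below one half.
    """
    if not (0.0 < threshold <= 1.0) or not (0.0 < band_low < threshold):
        raise ValueError("need 0 < band_low < threshold <= 1")
    cham = [(k, d) for k, d in delta.entries.items() if abs(d) > threshold]
    border = [(k, d) for k, d in delta.entries.items()
              if band_low <= abs(d) <= threshold]
    key = lambda kv: (-abs(kv[1]), kv[0].donor, kv[0].acceptor)
    return ChameleonReport(sorted(cham, key=key), sorted(border, key=key),
                           threshold=threshold, band_low=band_low)


def windowed_propensity(frames: TrajectoryFrames, bond: BondKey,
                        criterion: HBCriterion = HBCriterion(),
                        n_windows: int = 1) -> list[float]:
    """Formation fraction in contiguous time windows.

    Frames are split into ``n_windows`` blocks of equal size; remainder
    frames go to the last block.  Useful to expose the timescale on which
    a bond becomes stabilized during a binding run.
    """
    n = len(frames)
    if not (1 <= n_windows <= n):
        raise ValueError(f"n_windows must be in [1, {n}], got {n_windows}")
    states = np.array([_bond_geometry(f, bond, criterion)
                       for f in frames.frames], dtype=float)
    block = n // n_windows
    out = []
    for w in range(n_windows):
        lo = w * block
        hi = (w + 1) * block if w < n_windows - 1 else n
        out.append(float(states[lo:hi].mean()))
    return out
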