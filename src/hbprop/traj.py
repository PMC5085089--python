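"""Trajectory loading behind the TrajectoryFrames contract.

The baseline interchange format is multi-model PDB (one MODEL block per
frame).  Binary trajectory formats (DCD, XTC, ...) are supported through
an optional MDAnalysis adapter that maps onto the same contract; the
import is lazy so MDAnalysis is only needed when that route is used.
"""

from __future__ import annotations

import numpy as np

from .hbond import TrajectoryFrames
from .structure import (BackboneStructure, Residue, ResidueRef,
                        StructureError, parse_pdb_backbone)

__all__ = ["load_multimodel_pdb_frames", "frames_from_mdanalysis"]


def load_multimodel_pdb_frames(pdb_text: str,
                               frame_stride_ps: float | None = None
                               ) -> TrajectoryFrames:
    """Read every MODEL block of a PDB file as one trajectory frame."""
    n_models = max(pdb_text.count("\nMODEL"),
                   1 if pdb_text.startswith("MODEL") else 0, 1)
    frames = [parse_pdb_backbone(pdb_text, model_index=m)
              for m in range(1, n_models + 1)]
    return TrajectoryFrames(frames, frame_stride_ps=frame_stride_ps)


def frames_from_mdanalysis(universe, start: int = 0, stop: int | None = None,
                           step: int = 1) -> TrajectoryFrames:
    """Adapt an MDAnalysis Universe (any format it reads) to frames.

    Only protein backbone heavy atoms and amide hydrogens named 'H' are
    carried over; coordinates are in Angstrom as MDAnalysis reports them.
    """
    try:
        import MDAnalysis  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "frames_from_mdanalysis requires the MDAnalysis package") from exc
    protein = universe.select_atoms("protein")
    if protein.n_atoms == 0:
        raise StructureError("universe contains no protein atoms")
    keep = ("N", "CA", "C", "O", "CB", "H")
    frames = []
    for _ in universe.trajectory[start:stop:step]:
        residues = []
        prev_chain = None
        for res in protein.residues:
            chain = (getattr(res, "segid", "") or "A").strip() or "A"
            atoms = {a.name: np.array(a.position, dtype=float)
                     for a in res.atoms if a.name in keep}
            ref = ResidueRef(chain, int(res.resid), "", str(res.resname))
            donor = ref.res_name != "PRO" and chain == prev_chain
            prev_chain = chain
            residues.append(Residue(ref, atoms, donor_capable=donor))
        frames.append(BackboneStructure(residues, source_label="mdanalysis"))
    return TrajectoryFrames(frames)
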