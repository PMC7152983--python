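"""Least-squares superposition and the RMSD/RMSF metric family.

Implements Kabsch rigid-body fitting (SVD form), per-frame RMSD series
against a reference, per-residue RMSF about the ensemble mean (two-pass
fit), and sub-range RMSD (e.g. the activation helix, helix 12, of a
nuclear-receptor ligand-binding domain) with a coarse histogram.

No mass weighting is applied anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import FrameSeries, Selection, SelectionError, Topology, select


class FitError(ValueError):
    """Degenerate geometry or too few points for a rigid fit."""


class WindowError(ValueError):
    """An equilibration cut or window removed all usable frames."""


#: Default activation-helix (helix-12) residue ranges per receptor subtype.
HELIX12_RANGES = {"alpha": (448, 468), "beta": (421, 441), "gamma": (457, 477)}


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float  # post-fit, Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid transform to an (n, 3) coordinate array."""
        return coords @ self.rotation.T + self.translation


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Classic Kabsch algorithm: centroids removed, rotation from the SVD of
    the cross-covariance with a proper-rotation sign correction.  The
    returned rmsd is the post-fit residual.

    Raises :class:`FitError` for fewer than 3 points or (near-)collinear
    point sets, where the rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise FitError("point sets must both have shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise FitError("rigid fit requires at least 3 points")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    x = mobile - cm
    y = reference - cr
    h = x.T @ y
    # collinear sets leave the rotation about the line undetermined
    if _collinear(x) or _collinear(y):
        raise FitError("degenerate (collinear) geometry; rotation not unique")
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    fitted = x @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=cr - rot @ cm, rmsd=rmsd)


def _collinear(centered: np.ndarray) -> bool:
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[0] > 0 and s[1] / s[0] < 1e-8)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsd_series(
    series: FrameSeries,
    reference: np.ndarray,
    fit_selection: Selection,
    measure_selection: Selection | None = None,
) -> np.ndarray:
    """Per-frame RMSD after fitting ``fit_selection`` onto the reference.

    ``reference`` is a full-atom (n_atoms, 3) coordinate frame congruent
    with the series.  The frame is fitted on ``fit_selection`` and the
    RMSD measured on ``measure_selection`` (defaults to the fit
    selection).  Ligand-RMSD mode is this with a protein fit selection
    and a ligand measure selection.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (series.n_atoms, 3):
        raise ValueError("reference must be a full (n_atoms, 3) frame")
    if measure_selection is None:
        measure_selection = fit_selection
    fi = fit_selection.as_array()
    mi = measure_selection.as_array()
    if len(fi) == 0 or len(mi) == 0:
        raise ValueError("fit and measure selections must be non-empty")
    out = np.empty(series.n_frames)
    ref_fit = reference[fi]
    ref_meas = reference[mi]
    for f in range(series.n_frames):
        fit = kabsch_fit(series.coords[f, fi], ref_fit)
        out[f] = _rmsd(fit.apply(series.coords[f, mi]), ref_meas)
    return out


def _cut_index(series: FrameSeries, equilibration_cut: float | None) -> int:
    """First frame index to keep. None → discard the first half."""
    if equilibration_cut is None:
        return series.n_frames // 2
    start = int(np.searchsorted(series.times, equilibration_cut, side="left"))
    return start


def superpose_series(
    series: FrameSeries, fit_selection: Selection, start: int = 0
) -> np.ndarray:
    """Two-pass ensemble alignment.

    Frames from ``start`` on are fitted (on the fit selection) first to
    the first kept frame, then re-fitted to the resulting mean structure.
    Returns the aligned full-atom coordinates, shape (n_kept, n_atoms, 3).
    """
    fi = fit_selection.as_array()
    if len(fi) < 3:
        raise FitError("fit selection needs at least 3 atoms")
    coords = series.coords[start:]
    if coords.shape[0] < 1:
        raise WindowError("no frames left after equilibration cut")
    aligned = np.empty_like(coords)
    ref = coords[0, fi]
    for f in range(coords.shape[0]):
        aligned[f] = kabsch_fit(coords[f, fi], ref).apply(coords[f])
    mean_fit = aligned[:, fi].mean(axis=0)
    for f in range(coords.shape[0]):
        aligned[f] = kabsch_fit(coords[f, fi], mean_fit).apply(coords[f])
    return aligned


def rmsf_profile(
    series: FrameSeries,
    topology: Topology,
    selection: Selection,
    fit_selection: Selection | None = None,
    equilibration_cut: float | None = None,
) -> dict[str, float]:
    """Per-key RMSF in Å about the ensemble mean.

    RMSF_i = sqrt(mean_t |r_i(t) − ⟨r_i⟩|²) after two-pass fitting of the
    fit selection to the ensemble mean.  Keys are residue labels
    (``VAL_332``) when the selection has at most one atom per residue,
    otherwise ``RESNAME_NUM:ATOMNAME``.

    ``equilibration_cut`` is a time in ns below which frames are
    discarded; by default the first half of the trajectory is dropped.
    """
    if fit_selection is None:
        fit_selection = selection
    start = _cut_index(series, equilibration_cut)
    if series.n_frames - start < 2:
        raise WindowError("fewer than 2 frames after equilibration cut")
    aligned = superpose_series(series, fit_selection, start=start)
    idx = selection.as_array()
    sub = aligned[:, idx]
    mean = sub.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))
    keys = _selection_keys(topology, idx)
    return dict(zip(keys, rmsf.tolist()))


def _selection_keys(topology: Topology, idx: np.ndarray) -> list[str]:
    residues = [topology.atoms[i] for i in idx]
    res_ids = [(a.chain_id, a.residue_number, a.residue_name) for a in residues]
    per_res = len(set(res_ids)) == len(res_ids)
    keys = []
    for a in residues:
        base = f"{a.residue_name}_{a.residue_number}"
        keys.append(base if per_res else f"{base}:{a.name}")
    return keys


def subrange_rmsd(
    series: FrameSeries,
    topology: Topology,
    crystal_reference: np.ndarray,
    residue_range: tuple[int, int],
    fit_selection: Selection,
    bin_width: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RMSD of a residue sub-range's Cα after a global fit.

    Each frame is fitted on ``fit_selection`` to the crystal reference;
    the RMSD is then measured on the Cα atoms of the inclusive residue
    range.  Returns (per-frame rmsd, histogram counts, bin edges) with
    ``bin_width``-Å bins from zero.
    """
    lo, hi = residue_range
    sub = select(topology, f"name CA and resid {lo}:{hi}", label=f"CA {lo}-{hi}")
    if len(sub) < 3:
        raise SelectionError(f"residue range {lo}-{hi} resolves to {len(sub)} Cα atoms (<3)")
    series_rmsd = rmsd_series(series, crystal_reference, fit_selection, sub)
    top = max(bin_width, float(np.ceil(series_rmsd.max() / bin_width)) * bin_width)
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, edges = np.histogram(series_rmsd, bins=edges)
    return series_rmsd, counts, edges
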