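"""Dynamic time warping distances between strides.

Stance durations vary from step to step, so strides of one subject are time
series of different lengths.  Classic DTW aligns two series with a monotone
warping path and reports the minimal accumulated cost of the alignment; that
cost of imitation is used here as the dissimilarity between strides.

Conventions (documented, since several DTW variants exist):

* local cost is the absolute difference ``|a_i - b_j|`` (L1);
* steps are the symmetric unit-weight set {(1,0), (0,1), (1,1)}, each step
  adding the local cost of the cell it lands on;
* endpoints are anchored, no window by default (series are short); an
  optional Sakoe-Chiba band on the index difference is available;
* forces are normalized to fraction of body weight before alignment so that
  heavier subjects do not dominate the costs.

The per-phase distance sums the three per-component DTW costs (Fx, Fy, Fz)
over the phase window of one limb; the whole-stride distance sums the six
per-component full-stance costs (3 components x 2 limbs), each aligned
independently.  DTW is a dissimilarity, not a metric: it is nonnegative,
symmetric under this step set, and zero for identical series, but the
triangle inequality does not hold in general.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .phases import segment_stance
from .types import COMPONENTS, LIMBS, GRFSeries, StrideRecord

#: Column order of the distance profile: the five rho values.
PROFILE_COLUMNS = ("rho_MSt_L", "rho_TSt_L", "rho_MSt_R", "rho_TSt_R", "rho_Stride")

_PHASE_TO_SLOT = {"MSt": 0, "TSt": 1}


@njit(cache=True)
def _dtw_l1(a, b, band):  # pragma: no cover - executed through dispatcher
    n = a.shape[0]
    m = b.shape[0]
    big = 1e300
    prev = np.empty(m)
    cur = np.empty(m)
    acc = 0.0
    for j in range(m):
        if band >= 0 and j > band:
            prev[j] = big
        else:
            acc += abs(a[0] - b[j])
            prev[j] = acc
    for i in range(1, n):
        for j in range(m):
            if band >= 0 and abs(i - j) > band:
                cur[j] = big
                continue
            c = abs(a[i] - b[j])
            if j == 0:
                best = prev[0]
            else:
                best = prev[j]
                if prev[j - 1] < best:
                    best = prev[j - 1]
                if cur[j - 1] < best:
                    best = cur[j - 1]
            cur[j] = c + best
        prev, cur = cur, prev
    return prev[m - 1]


@njit(cache=True)
def _profile_tensor(pa, pn, pb, ga, gn, gb, band):  # pragma: no cover
    """All five distances for every probe x gallery stride pair.

    ``pa``/``ga`` are stacked normalized force arrays of shape
    ``(k, 6, max_len)``; ``pn``/``gn`` the true lengths; ``pb``/``gb`` the
    three interior phase boundaries (LR|MSt, MSt|TSt, TSt|PSw) per stride.
    """
    np_ = pa.shape[0]
    ng = ga.shape[0]
    out = np.zeros((np_, ng, 5))
    for i in range(np_):
        n = pn[i]
        p1, p2, p3 = pb[i, 0], pb[i, 1], pb[i, 2]
        for j in range(ng):
            m = gn[j]
            g1, g2, g3 = gb[j, 0], gb[j, 1], gb[j, 2]
            mst_l = 0.0
            tst_l = 0.0
            mst_r = 0.0
            tst_r = 0.0
            whole = 0.0
            for c in range(3):
                mst_l += _dtw_l1(pa[i, c, p1:p2], ga[j, c, g1:g2], band)
                tst_l += _dtw_l1(pa[i, c, p2:p3], ga[j, c, g2:g3], band)
                mst_r += _dtw_l1(pa[i, 3 + c, p1:p2], ga[j, 3 + c, g1:g2], band)
                tst_r += _dtw_l1(pa[i, 3 + c, p2:p3], ga[j, 3 + c, g2:g3], band)
            for c in range(6):
                whole += _dtw_l1(pa[i, c, :n], ga[j, c, :m], band)
            out[i, j, 0] = mst_l
            out[i, j, 1] = tst_l
            out[i, j, 2] = mst_r
            out[i, j, 3] = tst_r
            out[i, j, 4] = whole
    return out


def _as_array(series) -> np.ndarray:
    if isinstance(series, GRFSeries):
        arr = series.samples
    else:
        arr = np.asarray(series, dtype=np.float64)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("DTW input must be a non-empty one-dimensional series")
    return np.ascontiguousarray(arr, dtype=np.float64)


def dtw_cost(a, b, band: int | None = None) -> float:
    """Minimal accumulated L1 alignment cost between two series.

    ``a`` and ``b`` may be :class:`~gaitid.types.GRFSeries` (which must then
    agree on component and limb) or plain 1-D arrays.  ``band`` restricts
    the warping path to ``|i - j| <= band`` (Sakoe-Chiba); ``None`` means
    unconstrained.
    """
    if isinstance(a, GRFSeries) and isinstance(b, GRFSeries):
        if a.component != b.component or a.limb != b.limb:
            raise ValueError("series must describe the same component and limb")
    xa, xb = _as_array(a), _as_array(b)
    w = -1 if band is None else int(band)
    if w >= 0 and abs(xa.size - xb.size) > w:
        raise ValueError("band too narrow for the length difference")
    return float(_dtw_l1(xa, xb, w))


def phase_distance(
    probe: StrideRecord,
    gallery: StrideRecord,
    phase: str,
    limb: str,
    band: int | None = None,
) -> float:
    """Sum of the three per-component DTW costs over one phase of one limb."""
    if phase not in _PHASE_TO_SLOT:
        raise ValueError(f"phase must be 'MSt' or 'TSt', got {phase!r}")
    if limb not in LIMBS:
        raise ValueError(f"unknown limb {limb!r}")
    wp = next(w for w in segment_stance(probe.n_samples) if w.phase == phase)
    wg = next(w for w in segment_stance(gallery.n_samples) if w.phase == phase)
    total = 0.0
    for comp in COMPONENTS:
        a = probe.column(limb, comp)[wp.start_index : wp.end_index] / probe.body_weight_n
        b = gallery.column(limb, comp)[wg.start_index : wg.end_index] / gallery.body_weight_n
        total += dtw_cost(a, b, band=band)
    return total


def stride_distance(probe: StrideRecord, gallery: StrideRecord, band: int | None = None) -> float:
    """Sum of the six per-component full-stance DTW costs (both limbs)."""
    total = 0.0
    for limb in LIMBS:
        for comp in COMPONENTS:
            a = probe.column(limb, comp) / probe.body_weight_n
            b = gallery.column(limb, comp) / gallery.body_weight_n
            total += dtw_cost(a, b, band=band)
    return total


def _stack(strides: Sequence[StrideRecord]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    lengths = np.array([s.n_samples for s in strides], dtype=np.int64)
    max_len = int(lengths.max())
    arr = np.zeros((len(strides), 6, max_len), dtype=np.float64)
    bounds = np.zeros((len(strides), 3), dtype=np.int64)
    for i, s in enumerate(strides):
        arr[i, :, : s.n_samples] = s.normalized_forces().T
        wins = segment_stance(s.n_samples)
        bounds[i] = (wins[0].end_index, wins[1].end_index, wins[2].end_index)
    return arr, lengths, bounds


def profile_tensor(
    probes: Sequence[StrideRecord],
    gallery: Sequence[StrideRecord],
    band: int | None = None,
) -> np.ndarray:
    """Distance tensor of shape ``(n_probes, n_gallery, 5)``.

    The last axis follows :data:`PROFILE_COLUMNS`.  This is the bulk entry
    point used by the evaluation harness; :func:`distance_profile` wraps it
    for a single probe.
    """
    if len(probes) == 0 or len(gallery) == 0:
        raise ValueError("probe and gallery collections must be non-empty")
    pa, pn, pb = _stack(probes)
    ga, gn, gb = _stack(gallery)
    w = -1 if band is None else int(band)
    return _profile_tensor(pa, pn, pb, ga, gn, gb, w)


def distance_profile(
    probe: StrideRecord,
    gallery: Sequence[StrideRecord],
    band: int | None = None,
) -> pd.DataFrame:
    """Five DTW distances from one probe stride to every gallery stride.

    Rows follow the gallery enrollment order; the index carries the gallery
    subject labels.
    """
    tensor = profile_tensor([probe], gallery, band=band)
    return pd.DataFrame(
        tensor[0],
        columns=list(PROFILE_COLUMNS),
        index=pd.Index([g.subject_id for g in gallery], name="subject_id"),
    )
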