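"""Equal-width discretization, plug-in entropies, MI, CMI, interaction
information, and the permutation significance test.

All information quantities are plug-in estimates in *nats* computed from
contingency counts of equal-width discretized sample vectors. Interaction
information here follows the convention II = CMI - MI: a negative II says the
dependency between two taxa weakens once the environmental factor is known,
i.e. part of their association is environmentally driven.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscretizedVector",
    "DegenerateInputError",
    "equal_width_discretize",
    "contingency_counts",
    "entropy",
    "mutual_information",
    "conditional_mutual_information",
    "interaction_information",
    "ii_significance",
]

_NEG_TOL = 1e-12  # plug-in MI/CMI are analytically >= 0; clamp fp noise


class DegenerateInputError(ValueError):
    """Vector cannot be discretized (constant, or too short)."""


@dataclass(frozen=True)
class DiscretizedVector:
    """Integer bin labels for one sample vector.

    Labels lie in {0, ..., bin_count}; label 0 occurs only for the minimum
    value (the ceiling of 0). Only equality of labels matters downstream, so
    labels are used as-is without remapping.
    """

    bins: np.ndarray
    bin_count: int
    v_min: float
    v_max: float

    def __len__(self) -> int:
        return len(self.bins)


def equal_width_discretize(
    x: np.ndarray, range_denominator: bool = False
) -> DiscretizedVector:
    """Discretize a real vector into |B| = floor(sqrt(n)) equal-width bins.

    The bin label is ceil((v - v_min) * |B| / denom) with denom = v_max when
    v_min >= 0 and denom = v_max - v_min when v_min < 0. Setting
    ``range_denominator`` uses v_max - v_min in both cases.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise DegenerateInputError(f"need n >= 4 samples to discretize, got {n}")
    v_min = float(np.min(x))
    v_max = float(np.max(x))
    if v_min == v_max:
        raise DegenerateInputError("constant vector cannot be discretized")
    bin_count = int(np.floor(np.sqrt(n)))
    if range_denominator or v_min < 0:
        denom = v_max - v_min
    else:
        denom = v_max
    scaled = (x - v_min) * bin_count / denom
    bins = np.ceil(scaled - 1e-12).astype(np.int64)  # guard fp overshoot at edges
    bins = np.clip(bins, 0, bin_count)
    return DiscretizedVector(bins=bins, bin_count=bin_count, v_min=v_min, v_max=v_max)


def contingency_counts(*labels: np.ndarray) -> np.ndarray:
    """Joint contingency table (1-3 axes) from integer label vectors."""
    if not 1 <= len(labels) <= 3:
        raise ValueError("contingency_counts takes 1 to 3 label vectors")
    arrays = [np.asarray(l, dtype=np.int64) for l in labels]
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("label vectors have mismatched lengths")
    dims = tuple(int(a.max()) + 1 for a in arrays)
    flat = np.zeros(1, dtype=np.int64)
    code = np.zeros(n, dtype=np.int64)
    for a, d in zip(arrays, dims):
        code = code * d + a
    flat = np.bincount(code, minlength=int(np.prod(dims)))
    return flat.reshape(dims)


def entropy(counts: np.ndarray) -> float:
    """Plug-in Shannon entropy in nats of a (1-3 dim) contingency table."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("negative count in contingency table")
    total = counts.sum()
    if total <= 0:
        raise ValueError("contingency table is empty")
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log(p)))


def _check_same_length(*vectors) -> None:
    lengths = {len(v) for v in vectors}
    if len(lengths) > 1:
        raise ValueError(f"length mismatch: {sorted(lengths)}")


def mutual_information(vd: DiscretizedVector, wd: DiscretizedVector) -> float:
    """MI(v; w) = S(v) + S(w) - S(v, w), clamped to >= 0."""
    _check_same_length(vd, wd)
    s_v = entropy(contingency_counts(vd.bins))
    s_w = entropy(contingency_counts(wd.bins))
    s_vw = entropy(contingency_counts(vd.bins, wd.bins))
    mi = s_v + s_w - s_vw
    return 0.0 if mi < _NEG_TOL else mi


def conditional_mutual_information(
    vd: DiscretizedVector, wd: DiscretizedVector, fd: DiscretizedVector
) -> float:
    """CMI(v; w | f) = S(v,f) + S(w,f) - S(v,w,f) - S(f), clamped to >= 0."""
    _check_same_length(vd, wd, fd)
    s_vf = entropy(contingency_counts(vd.bins, fd.bins))
    s_wf = entropy(contingency_counts(wd.bins, fd.bins))
    s_vwf = entropy(contingency_counts(vd.bins, wd.bins, fd.bins))
    s_f = entropy(contingency_counts(fd.bins))
    cmi = s_vf + s_wf - s_vwf - s_f
    return 0.0 if cmi < _NEG_TOL else cmi


def interaction_information(
    v: np.ndarray, w: np.ndarray, f: np.ndarray, range_denominator: bool = False
) -> tuple[float, float, float]:
    """II = CMI - MI on equal-width discretized raw vectors.

    Returns (ii, mi, cmi).
    """
    _check_same_length(v, w, f)
    vd = equal_width_discretize(v, range_denominator)
    wd = equal_width_discretize(w, range_denominator)
    fd = equal_width_discretize(f, range_denominator)
    mi = mutual_information(vd, wd)
    cmi = conditional_mutual_information(vd, wd, fd)
    return cmi - mi, mi, cmi


def _cmi_permuted_batch(
    v_bins: np.ndarray, w_bins: np.ndarray, f_perms: np.ndarray
) -> np.ndarray:
    """CMI(v; w | f_perm) for a (P, n) batch of permuted f labels, vectorized.

    Counts every joint table for all P permutations with one bincount over
    combined (perm, v, w, f) codes.
    """
    P, n = f_perms.shape
    dv = int(v_bins.max()) + 1
    dw = int(w_bins.max()) + 1
    df = int(f_perms.max()) + 1
    base = np.arange(P, dtype=np.int64)[:, None]

    def batched_entropy(code: np.ndarray, n_cells: int) -> np.ndarray:
        flat = np.bincount(
            (base * n_cells + code).ravel(), minlength=P * n_cells
        ).reshape(P, n_cells)
        p = flat / n
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        return -terms.sum(axis=1)

    vf_code = v_bins[None, :] * df + f_perms
    wf_code = w_bins[None, :] * df + f_perms
    vwf_code = (v_bins * dw + w_bins)[None, :] * df + f_perms
    s_vf = batched_entropy(vf_code, dv * df)
    s_wf = batched_entropy(wf_code, dw * df)
    s_vwf = batched_entropy(vwf_code, dv * dw * df)
    s_f = batched_entropy(f_perms, df)
    cmi = s_vf + s_wf - s_vwf - s_f
    return np.where(cmi < _NEG_TOL, 0.0, cmi)


def ii_significance(
    v: np.ndarray,
    w: np.ndarray,
    f: np.ndarray,
    iterations: int = 1000,
    rng: np.random.Generator | None = None,
    range_denominator: bool = False,
) -> float:
    """Permutation p-value for the interaction information.

    MI(v; w) does not involve f, so the significance of II equals that of the
    CMI. The factor vector is permuted uniformly ``iterations`` times, the
    CMI recomputed each time, and with c = #{CMI_i <= CMI_original} the
    p-value is (c + 1) / (iterations + 1).
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    _check_same_length(v, w, f)
    vd = equal_width_discretize(v, range_denominator)
    wd = equal_width_discretize(w, range_denominator)
    fd = equal_width_discretize(f, range_denominator)
    cmi_orig = conditional_mutual_information(vd, wd, fd)
    n = len(fd.bins)
    perms = np.empty((iterations, n), dtype=np.int64)
    for i in range(iterations):
        perms[i] = fd.bins[rng.permutation(n)]
    cmi_perm = _cmi_permuted_batch(vd.bins, wd.bins, perms)
    c = int(np.count_nonzero(cmi_perm <= cmi_orig + 1e-12))
    return (c + 1) / (iterations + 1)
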