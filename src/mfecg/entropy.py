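"""Generalized multiscale sample entropy.

A series is coarse-grained at scale ``s`` by replacing non-overlapping
blocks of length ``s`` with a block statistic — the mean (first moment,
MSEN1) or the unbiased variance (second moment, MSEN2) — and the sample
entropy of the coarse-grained series is computed per scale with the
matching tolerance ``r`` taken as a fraction of *that* series' standard
deviation (recomputed after coarse-graining, not inherited from scale 1).

Sample entropy here uses Chebyshev template matching with self-matches
excluded and per-order denominators Ns-m+1 (order m) and Ns-m (order m+1):

    SampEn(m, r) = -ln( A^{m+1}(r) / A^m(r) )

Undefined values (no template matches at either order) are reported as NaN
and are never imputed with zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial import cKDTree

__all__ = [
    "CoarseGrainedSeries",
    "MSEProfile",
    "coarse_grain",
    "sample_entropy",
    "mse_profile",
    "mse_feature",
    "MultiscaleEntropyExtractor",
]

DEFAULT_SCALES = tuple(range(10, 21))


@dataclass(frozen=True)
class CoarseGrainedSeries:
    """Block-statistic series at one scale."""

    values: np.ndarray
    scale: int
    moment: int
    source_length: int

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.values)


@dataclass(frozen=True)
class MSEProfile:
    """Sample entropy per coarse-graining scale (NaN where undefined)."""

    scales: np.ndarray
    entropy: np.ndarray
    moment: int
    m: int
    r_frac: float

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.entropy)


def coarse_grain(x: np.ndarray, s: int, moment: int = 1) -> CoarseGrainedSeries:
    """Coarse-grain ``x`` at scale ``s`` with the given moment statistic.

    moment 1: block means; moment 2: unbiased block variances (needs s >= 2).
    The trailing remainder of length N mod s is dropped.
    """
    x = np.asarray(x, dtype=float)
    if moment not in (1, 2):
        raise ValueError(f"moment must be 1 or 2, got {moment}")
    if s < 1:
        raise ValueError(f"scale must be >= 1, got {s}")
    if moment == 2 and s < 2:
        raise ValueError("variance coarse-graining needs scale >= 2 "
                         "(variance of a single point is undefined)")
    n_blocks = len(x) // s
    if n_blocks < 1:
        raise ValueError(f"series of length {len(x)} too short for scale {s}")
    blocks = x[: n_blocks * s].reshape(n_blocks, s)
    if moment == 1:
        values = blocks.mean(axis=1)
    else:
        values = blocks.var(axis=1, ddof=1)
    return CoarseGrainedSeries(values=values, scale=s, moment=moment,
                               source_length=len(x))


def _match_counts(y: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Unordered template-pair counts (i<j, Chebyshev distance < r) at
    orders m and m+1, via KD-trees on the embedded vectors."""
    # strict '<' matching: d < r  <=>  d <= nextafter(r, -inf) in floats
    r_closed = np.nextafter(r, -np.inf)
    counts = []
    for order in (m, m + 1):
        emb = sliding_window_view(y, order)
        tree = cKDTree(emb)
        total = tree.count_neighbors(tree, r_closed, p=np.inf)
        counts.append(int(total - len(emb)) // 2)
    return counts[0], counts[1]


def sample_entropy(y: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r) of ``y``; NaN when no matches exist at either order.

    ``r`` is an absolute tolerance in the units of ``y``.
    """
    y = np.asarray(y, dtype=float)
    if r is None or not r > 0:
        raise ValueError(f"tolerance r must be > 0, got {r}")
    if m < 1:
        raise ValueError(f"embedding dimension m must be >= 1, got {m}")
    n = len(y)
    if n < m + 2:
        raise ValueError(f"need at least m+2={m + 2} samples, got {n}")
    b_m, b_m1 = _match_counts(y, m, r)
    if b_m == 0 or b_m1 == 0:
        return float("nan")
    nt_m = n - m + 1
    nt_m1 = n - m
    a_m = 2.0 * b_m / (nt_m * nt_m)
    a_m1 = 2.0 * b_m1 / (nt_m1 * nt_m1)
    return float(-np.log(a_m1 / a_m))


def mse_profile(x: np.ndarray, scales, m: int = 2, r_frac: float = 0.15,
                moment: int = 1, r_mode: str = "scalewise") -> MSEProfile:
    """Sample entropy across coarse-graining scales.

    With ``r_mode='scalewise'`` (the default) the tolerance at each scale is
    ``r_frac`` times the standard deviation (ddof=1) of the coarse-grained
    series of that scale, so the entropy measures the *shape* of the
    coarse-grained fluctuations independent of their magnitude. The classic
    multiscale-entropy convention, ``r_mode='global'``, fixes the tolerance
    from the original series' standard deviation for all scales; under it,
    coarse-graining averages white noise below tolerance and its entropy
    falls with scale, while long-range-correlated (1/f) noise stays roughly
    flat. A degenerate constant coarse series has entropy 0 by convention;
    scales whose coarse series is too short, or where no templates match,
    yield NaN with a warning.
    """
    if r_mode not in ("scalewise", "global"):
        raise ValueError(f"r_mode must be 'scalewise' or 'global', got {r_mode!r}")
    x = np.asarray(x, dtype=float)
    scales = np.asarray(list(scales), dtype=int)
    out = np.full(len(scales), np.nan)
    sigma_global = x.std(ddof=1)
    for idx, s in enumerate(scales):
        try:
            cg = coarse_grain(x, int(s), moment=moment)
        except ValueError as exc:
            warnings.warn(f"scale {s}: {exc}", stacklevel=2)
            continue
        y = cg.values
        if len(y) < m + 2:
            warnings.warn(f"scale {s}: coarse series too short "
                          f"({len(y)} < {m + 2})", stacklevel=2)
            continue
        sigma = y.std(ddof=1) if r_mode == "scalewise" else sigma_global
        if np.ptp(y) == 0.0 or sigma == 0.0:  # constant coarse series
            out[idx] = 0.0
            continue
        out[idx] = sample_entropy(y, m=m, r=r_frac * sigma)
        if np.isnan(out[idx]):
            warnings.warn(f"scale {s}: undefined sample entropy "
                          "(no template matches)", stacklevel=2)
    return MSEProfile(scales=scales, entropy=out, moment=moment, m=m,
                      r_frac=r_frac)


def mse_feature(x: np.ndarray, scale_lo: int = 10, scale_hi: int = 20,
                m: int = 2, r_frac: float = 0.15, moment: int = 1) -> float:
    """Mean entropy over scales ``scale_lo..scale_hi`` (NaN entries skipped).

    Returns NaN if more than half the scales are undefined.
    """
    scales = range(scale_lo, scale_hi + 1)
    profile = mse_profile(x, scales, m=m, r_frac=r_frac, moment=moment)
    defined = profile.defined
    if defined.sum() * 2 <= len(profile.scales):
        return float("nan")
    return float(profile.entropy[defined].mean())


class MultiscaleEntropyExtractor:
    """Transformer mapping raw series to multiscale-entropy features.

    Parameters
    ----------
    scales : iterable of int, default 10..20
    m : embedding dimension (default 2)
    r_frac : tolerance as a fraction of the per-scale coarse-grained
        standard deviation (default 0.15)
    moment : 1 (mean) or 2 (unbiased variance) coarse-graining
    aggregate : if True (default), transform returns one column (the mean
        over scales); otherwise one column per scale.

    Stateless: ``fit`` only validates parameters. Accepts a 2-D array or a
    list of 1-D arrays (segments may have different lengths).
    """

    def __init__(self, scales=DEFAULT_SCALES, m: int = 2,
                 r_frac: float = 0.15, moment: int = 1,
                 aggregate: bool = True):
        self.scales = scales
        self.m = m
        self.r_frac = r_frac
        self.moment = moment
        self.aggregate = aggregate

    def get_params(self, deep: bool = True) -> dict:
        return {"scales": self.scales, "m": self.m, "r_frac": self.r_frac,
                "moment": self.moment, "aggregate": self.aggregate}

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y=None):
        if self.moment not in (1, 2):
            raise ValueError("moment must be 1 or 2")
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        scales = list(self.scales)
        rows = []
        for x in X:
            profile = mse_profile(np.asarray(x, dtype=float), scales,
                                  m=self.m, r_frac=self.r_frac,
                                  moment=self.moment)
            if self.aggregate:
                defined = profile.defined
                if defined.sum() * 2 <= len(scales):
                    rows.append([float("nan")])
                else:
                    rows.append([float(profile.entropy[defined].mean())])
            else:
                rows.append(profile.entropy.tolist())
        return np.asarray(rows, dtype=float)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
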