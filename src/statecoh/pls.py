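"""Mean-centered task PLS with permutation and bootstrap inference.

The model: observations are (block, subject) rows of a feature matrix
(coherence or power at every frequency-bin x node-pair/node).  Condition
(block) means are computed, the grand mean of the condition means is
removed, and the resulting condition-deviation matrix ``M`` is decomposed by
SVD::

    M = U S V'     (U: condition contrasts, V: feature saliences)

Each latent variable (LV) pairs one contrast column with one salience column;
its singular value measures how strongly that inter-block pattern is
expressed.  Inference:

* **Permutation test** — block labels are reshuffled (by default within each
  subject, respecting the fully within-subject design), the decomposition is
  recomputed, and each LV's p-value is the add-one-corrected fraction of
  permuted singular values at or above the observed one.
* **Bootstrap ratios (BSR)** — subjects are resampled with replacement (the
  same resample applied to every block, preserving pairing), saliences are
  recomputed and sign-aligned to the original, and each feature's BSR is its
  original salience divided by the bootstrap standard deviation — a pseudo-z
  reliability score whose sign gives the direction of the condition
  difference.

:class:`MeanCenteredPLS` is a scikit-learn style estimator (``fit`` /
``transform`` / ``get_params``); the module-level functions are thin wrappers
used by the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FeatureMatrix",
    "tensor_to_features",
    "mean_center",
    "pls_svd",
    "MeanCenteredPLS",
    "permutation_test",
    "bootstrap_bsr",
    "PLSResult",
    "run_pls",
]


@dataclass
class FeatureMatrix:
    """Flattened (block, subject) x feature data with labels.

    Every (condition, subject) combination must appear exactly once and no
    value may be missing.  ``feature_meta`` carries one row per column
    (frequency plus node-pair or node identity).
    """

    values: np.ndarray
    conditions: np.ndarray
    subjects: np.ndarray
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.conditions = np.asarray(self.conditions)
        self.subjects = np.asarray(self.subjects)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (observations x features)")
        n = self.values.shape[0]
        if len(self.conditions) != n or len(self.subjects) != n:
            raise ValueError("row label length mismatch")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        conds, subjs = np.unique(self.conditions), np.unique(self.subjects)
        if len(conds) < 2 or len(subjs) < 2:
            raise ValueError("need at least 2 conditions and 2 subjects")
        keys = set(zip(self.conditions.tolist(), self.subjects.tolist()))
        if len(keys) != n or n != len(conds) * len(subjs):
            raise ValueError("each (condition, subject) must appear exactly once")


def tensor_to_features(tensor: xr.DataArray) -> FeatureMatrix:
    """Flatten a 4-D spectral tensor to (block, subject) rows x (freq, channel) columns.

    Works for both coherence (channel = node-pair) and power (channel = node)
    tensors; column labels are preserved in ``feature_meta``.
    """
    dims = tensor.dims
    if dims[:3] != ("block", "subject", "freq") or len(dims) != 4:
        raise ValueError(f"expected dims (block, subject, freq, channel), got {dims}")
    if np.isnan(tensor.values).any():
        raise ValueError(
            "tensor contains flagged-missing values; resolve degenerate bins "
            "before PLS"
        )
    chan = dims[3]
    n_b, n_s, n_f, n_c = tensor.shape
    values = tensor.values.reshape(n_b * n_s, n_f * n_c)
    blocks = np.repeat(np.asarray(tensor["block"].values, dtype=object), n_s)
    subjects = np.tile(np.asarray(tensor["subject"].values, dtype=object), n_b)
    meta = {"freq": np.repeat(tensor["freq"].values, n_c)}
    if chan == "pair":
        meta["node_i"] = np.tile(tensor["node_i"].values, n_f)
        meta["node_j"] = np.tile(tensor["node_j"].values, n_f)
    else:
        meta["node"] = np.tile(tensor["node"].values, n_f)
    return FeatureMatrix(values, blocks, subjects, pd.DataFrame(meta))


def _arrange(X: FeatureMatrix) -> tuple[np.ndarray, list, list]:
    """Reshape to D (n_cond, n_subj, n_feat).

    Condition order is first appearance (block order is meaningful for the
    contrasts); subject order is sorted so row order in the input cannot
    perturb the subject-mean accumulation (exact permutation invariance).
    """
    conds = list(dict.fromkeys(X.conditions.tolist()))
    subjs = sorted(set(X.subjects.tolist()), key=str)
    c_idx = {c: i for i, c in enumerate(conds)}
    s_idx = {s: i for i, s in enumerate(subjs)}
    D = np.empty((len(conds), len(subjs), X.values.shape[1]))
    for row, (c, s) in enumerate(zip(X.conditions, X.subjects)):
        D[c_idx[c], s_idx[s]] = X.values[row]
    return D, conds, subjs


def _deviation(D: np.ndarray) -> np.ndarray:
    """Condition means minus the grand mean of condition means."""
    R = D.mean(axis=1)
    return R - R.mean(axis=0, keepdims=True)


def mean_center(X: FeatureMatrix) -> tuple[np.ndarray, list]:
    """Condition-deviation matrix (conditions x features) and condition order.

    Row c is (mean over subjects of condition c) minus the grand mean of the
    condition means; every column sums to zero across conditions.
    """
    D, conds, _ = _arrange(X)
    return _deviation(D), conds


def pls_svd(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of a condition-deviation matrix, restricted to nonzero singular values.

    Returns (singular_values, contrasts, saliences) with
    ``M ~= contrasts @ diag(singular_values) @ saliences.T``.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite deviation matrix")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep = s > max(tol, 1e-14)
    return s[keep], U[:, keep], Vt[keep].T


def _svd_fixed(M: np.ndarray, n_lv: int):
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return s[:n_lv], U[:, :n_lv], Vt[:n_lv].T


class MeanCenteredPLS(TransformerMixin, BaseEstimator):
    """Mean-centered task PLS across experimental conditions.

    Parameters
    ----------
    n_perm : int
        Permutations for the LV significance test (0 skips it).
    n_boot : int
        Bootstrap iterations for feature reliability (0 skips it).
    random_state : int or None
        One seed drives both resampling schemes through independent derived
        streams, so changing ``n_perm`` never alters the bootstrap draws.
    permute : {"within_subject", "pooled"}
        Exchange unit of the permutation test.  The design is fully
        within-subject, so by default each subject's block labels are
        shuffled among that subject's own observations; "pooled" shuffles
        whole rows across the sample (sensitivity variant).
    align : {"sign", "procrustes"}
        How bootstrap saliences are matched to the original before the
        standard deviation is taken (SVD sign/rotation indeterminacy).
    weighted_saliences : bool
        If True, BSRs are computed on singular-value-weighted saliences.

    Attributes
    ----------
    conditions_, subjects_ : label order (first appearance).
    singular_values_ : (n_lv,) non-increasing.
    contrasts_ : (n_conditions, n_lv) left singular vectors.
    saliences_ : (n_features, n_lv) right singular vectors.
    perm_p_ : (n_lv,) add-one permutation p-values (None if n_perm=0).
    bsr_ : (n_features, n_lv) bootstrap ratios (None if n_boot=0).
    boot_skipped_ : bootstrap samples discarded for a degenerate (all-zero)
        deviation matrix.
    """

    def __init__(
        self,
        n_perm: int = 512,
        n_boot: int = 512,
        random_state: int | None = None,
        permute: str = "within_subject",
        align: str = "sign",
        weighted_saliences: bool = False,
    ):
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.random_state = random_state
        self.permute = permute
        self.align = align
        self.weighted_saliences = weighted_saliences

    # -- internals ----------------------------------------------------------

    def _streams(self) -> tuple[np.random.Generator, np.random.Generator]:
        root = np.random.SeedSequence(self.random_state)
        perm_ss, boot_ss = root.spawn(2)
        return np.random.default_rng(perm_ss), np.random.default_rng(boot_ss)

    def _perm_singulars(self, D, n_lv, rng):
        C, S, _ = D.shape
        if self.permute == "within_subject":
            perms = np.stack([rng.permutation(C) for _ in range(S)], axis=1)  # (C, S)
            Dp = D[perms, np.arange(S)[None, :], :]
        elif self.permute == "pooled":
            flat = D.reshape(C * S, -1)
            Dp = flat[rng.permutation(C * S)].reshape(D.shape)
        else:
            raise ValueError(f"unknown permute mode {self.permute!r}")
        return np.linalg.svd(_deviation(Dp), compute_uv=False)[:n_lv]

    # -- API ----------------------------------------------------------------

    def fit(self, X, y=None, groups=None):
        """Fit on a feature matrix.

        ``X`` may be a :class:`FeatureMatrix` (then ``y``/``groups`` are
        ignored) or a 2-D array with ``y`` the condition label and ``groups``
        the subject id of each row.
        """
        if isinstance(X, FeatureMatrix):
            fm = X
        else:
            if y is None or groups is None:
                raise ValueError("array input requires y (conditions) and groups (subjects)")
            fm = FeatureMatrix(np.asarray(X), np.asarray(y), np.asarray(groups))
        if self.n_perm < 0 or self.n_boot < 0:
            raise ValueError("n_perm and n_boot must be non-negative")

        D, conds, subjs = _arrange(fm)
        C, S, F = D.shape
        n_lv = min(C - 1, F)
        M = _deviation(D)
        s, U, V = _svd_fixed(M, n_lv)

        self.conditions_ = conds
        self.subjects_ = subjs
        self.n_features_in_ = F
        self.singular_values_ = s
        self.contrasts_ = U
        self.saliences_ = V

        perm_rng, boot_rng = self._streams()

        self.perm_p_ = None
        if self.n_perm > 0:
            exceed = np.zeros(n_lv)
            for _ in range(self.n_perm):
                exceed += self._perm_singulars(D, n_lv, perm_rng) >= s
            self.perm_p_ = (1.0 + exceed) / (1.0 + self.n_perm)

        self.bsr_ = None
        self.boot_skipped_ = 0
        if self.n_boot > 0:
            self.bsr_ = self._bootstrap(D, s, V, boot_rng)
        return self

    def _bootstrap(self, D, s, V, rng):
        C, S, F = D.shape
        n_lv = V.shape[1]
        ref = V * s if self.weighted_saliences else V
        acc = np.zeros((F, n_lv))
        acc2 = np.zeros((F, n_lv))
        used = 0
        for _ in range(self.n_boot):
            idx = rng.integers(0, S, size=S)
            Mb = _deviation(D[:, idx, :])
            if not Mb.any():
                self.boot_skipped_ += 1
                continue
            sb, _, Vb = _svd_fixed(Mb, n_lv)
            Wb = Vb * sb if self.weighted_saliences else Vb
            Wb = self._align(Wb, ref)
            acc += Wb
            acc2 += Wb**2
            used += 1
        if used < 2:
            raise ValueError("fewer than 2 usable bootstrap samples")
        if self.boot_skipped_ > 0.01 * self.n_boot:
            warnings.warn(
                f"{self.boot_skipped_}/{self.n_boot} bootstrap samples had a "
                "degenerate deviation matrix and were skipped"
            )
        mean = acc / used
        var = np.maximum(acc2 / used - mean**2, 0.0) * used / (used - 1)
        sd = np.sqrt(var)
        with np.errstate(divide="ignore", invalid="ignore"):
            bsr = ref / sd
        # zero bootstrap variance: flagged infinite (sign of the salience)
        bsr = np.where(sd == 0, np.sign(ref) * np.inf, bsr)
        bsr = np.where((sd == 0) & (ref == 0), 0.0, bsr)
        # saliences at machine zero (e.g. a feature constant across the whole
        # design) are reported as BSR 0 rather than a ratio of rounding noise
        scale = np.sqrt(np.sum(ref**2, axis=0, keepdims=True))
        return np.where(np.abs(ref) <= 1e-10 * scale, 0.0, bsr)

    def _align(self, W, ref):
        if self.align == "sign":
            dots = np.sum(W * ref, axis=0)
            return W * np.where(dots < 0, -1.0, 1.0)
        if self.align == "procrustes":
            P, _, Qt = np.linalg.svd(W.T @ ref)
            return W @ (P @ Qt)
        raise ValueError(f"unknown align mode {self.align!r}")

    def transform(self, X):
        """Project observations onto the saliences (brain scores)."""
        check_is_fitted(self, "saliences_")
        values = X.values if isinstance(X, FeatureMatrix) else np.asarray(X)
        return values @ self.saliences_


def permutation_test(
    X: FeatureMatrix,
    n_perm: int = 512,
    seed: int | None = None,
    permute: str = "within_subject",
) -> np.ndarray:
    """Add-one permutation p-value per LV: (1 + #{s_perm >= s_obs}) / (1 + n_perm)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    est = MeanCenteredPLS(
        n_perm=n_perm, n_boot=0, random_state=seed, permute=permute
    ).fit(X)
    return est.perm_p_


def bootstrap_bsr(
    X: FeatureMatrix,
    n_boot: int = 512,
    seed: int | None = None,
    align: str = "sign",
    weighted_saliences: bool = False,
) -> np.ndarray:
    """Bootstrap ratios (features x LVs): salience / bootstrap std of salience."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    est = MeanCenteredPLS(
        n_perm=0,
        n_boot=n_boot,
        random_state=seed,
        align=align,
        weighted_saliences=weighted_saliences,
    ).fit(X)
    return est.bsr_


@dataclass
class PLSResult:
    """Full mean-centered PLS output with axis labels and provenance."""

    singular_values: np.ndarray
    contrasts: np.ndarray
    saliences: np.ndarray
    perm_p: np.ndarray | None
    bsr: np.ndarray | None
    conditions: list
    feature_meta: pd.DataFrame
    freqs: np.ndarray
    n_channels: int
    kind: str
    n_perm: int
    n_boot: int
    seed: int | None

    @property
    def n_lv(self) -> int:
        return len(self.singular_values)

    def bsr_map(self, lv: int = 0) -> np.ndarray:
        """BSR of one LV as a (n_freq, n_channels) map."""
        if self.bsr is None:
            raise ValueError("no bootstrap was run")
        return self.bsr[:, lv].reshape(len(self.freqs), self.n_channels)

    def salience_map(self, lv: int = 0) -> np.ndarray:
        return self.saliences[:, lv].reshape(len(self.freqs), self.n_channels)

    def oriented(self, positive_conditions: Sequence) -> "PLSResult":
        """Copy with each LV's sign fixed so the named conditions load positive.

        SVD signs are arbitrary; this orients every LV so the mean contrast
        over ``positive_conditions`` (e.g. the task blocks) exceeds the mean
        over the remaining conditions, making positive BSRs mean
        "greater during task".
        """
        pos = np.array([c in set(positive_conditions) for c in self.conditions])
        if not pos.any() or pos.all():
            raise ValueError("positive_conditions must be a proper subset")
        flips = np.ones(self.n_lv)
        for k in range(self.n_lv):
            diff = self.contrasts[pos, k].mean() - self.contrasts[~pos, k].mean()
            if diff < 0:
                flips[k] = -1.0
        return replace(
            self,
            contrasts=self.contrasts * flips,
            saliences=self.saliences * flips,
            bsr=None if self.bsr is None else self.bsr * flips,
        )


def run_pls(
    tensor: xr.DataArray,
    n_perm: int = 512,
    n_boot: int = 512,
    seed: int | None = None,
    **estimator_kw,
) -> PLSResult:
    """Mean-centered PLS of a coherence or power tensor.

    Flattens (freq x pair-or-node) into the feature axis, fits
    :class:`MeanCenteredPLS` and packages the result with labels.
    Deterministic given ``seed``.
    """
    fm = tensor_to_features(tensor)
    est = MeanCenteredPLS(
        n_perm=n_perm, n_boot=n_boot, random_state=seed, **estimator_kw
    ).fit(fm)
    chan_dim = tensor.dims[3]
    return PLSResult(
        singular_values=est.singular_values_,
        contrasts=est.contrasts_,
        saliences=est.saliences_,
        perm_p=est.perm_p_,
        bsr=est.bsr_,
        conditions=est.conditions_,
        feature_meta=fm.feature_meta,
        freqs=np.asarray(tensor["freq"].values, dtype=float),
        n_channels=tensor.shape[3],
        kind="coherence" if chan_dim == "pair" else "power",
        n_perm=n_perm,
        n_boot=n_boot,
        seed=seed,
    )
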