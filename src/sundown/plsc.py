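"""Behavioral partial least squares correlation (PLSC).

PLSC relates two blocks measured on the same subjects — a behavior block
``X`` (n subjects × p features) and a brain-activity block ``Y``
(n subjects × q regions, e.g. eYFP+ or c-Fos+ cell densities in cells/mm³) —
through the singular value decomposition of their cross-correlation matrix

    R = Zxᵀ Zy / (n − 1) = U diag(δ) Vᵀ,

where ``Zx`` and ``Zy`` are the column-standardized blocks.  Each pair of
singular vectors (a column of U and of V) is a *latent variable* (LV): the
behavioral and brain *saliences* weight the original features, and the
singular value δᵢ measures the cross-block covariance the LV captures.

Inference follows the standard two-step scheme:

* **Permutation test** — subject rows of the brain block are permuted
  relative to the behavior block; the null distribution of singular values
  gives a per-LV p-value and a 95th-percentile significance cutoff.
* **Bootstrap ratios** — subjects are resampled with replacement; each
  replicate's saliences are sign-aligned to the original and the bootstrap
  ratio BR = salience / SE(salience) is a z-like stability score.
  Features with |BR| > 2 are flagged as reliable contributors
  (|BR| = 2 approximates a 95% confidence interval).

The model/results split follows statsmodels: build a
:class:`BehavioralPLSC` from the two tables, call :meth:`~BehavioralPLSC.fit`,
and read estimates off the returned :class:`PLSCResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "impute_and_filter",
    "cross_correlation",
    "svd_saliences",
    "BehavioralPLSC",
    "PLSCResults",
    "LatentProjection",
]

_META_COLS = ("subject_id", "group")


def _feature_frame(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric feature columns of a subject table (drops subject_id/group)."""
    cols = [c for c in table.columns if c not in _META_COLS]
    return table[cols]


def impute_and_filter(
    table: pd.DataFrame,
    max_missing_per_group: int = 2,
    group_col: str = "group",
) -> pd.DataFrame:
    """Drop high-missingness regions and median-impute the rest group-wise.

    A region (feature column) is removed when *any* group is missing more
    than ``max_missing_per_group`` of its values.  Remaining missing entries
    are assumed missing at random and replaced by the median of the present
    values of that region within the subject's own group.

    Parameters
    ----------
    table
        Subject table with a ``group`` column and numeric region columns.
    max_missing_per_group
        Tolerated missing count per region per group (default 2); a region
        exceeding it in any group is dropped entirely.

    Returns
    -------
    pandas.DataFrame
        Copy of ``table`` with offending regions dropped and no missing
        values among the retained region columns.
    """
    if group_col not in table.columns:
        raise ValueError(f"table has no {group_col!r} column")
    groups = table[group_col]
    if groups.isna().any():
        raise ValueError("every subject needs a group label")
    sizes = groups.value_counts()
    too_small = sizes[sizes <= max_missing_per_group]
    if not too_small.empty:
        raise ValueError(
            "group(s) no larger than max_missing_per_group cannot be "
            f"imputed: {dict(too_small)}"
        )

    feats = _feature_frame(table)
    missing_per_group = feats.isna().groupby(groups, observed=True).sum()
    keep = missing_per_group.columns[(missing_per_group <= max_missing_per_group).all(axis=0)]

    out = table.copy()
    out = out.drop(columns=[c for c in feats.columns if c not in set(keep)])
    for col in keep:
        med = out.groupby(group_col, observed=True)[col].transform("median")
        out[col] = out[col].fillna(med)
    return out


def _standardize(A: np.ndarray, names) -> np.ndarray:
    """Column z-scores with ddof=1; raises naming any zero-variance column."""
    A = np.asarray(A, dtype=float)
    sd = A.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance column(s): {[names[i] for i in bad]}")
    return (A - A.mean(axis=0)) / sd


def cross_correlation(X: pd.DataFrame, Y: pd.DataFrame) -> pd.DataFrame:
    """Behavior × region Pearson cross-correlation matrix.

    Both blocks are column-standardized (centered and scaled), so each entry
    is the Pearson correlation between one behavior feature and one region
    across subjects.  Inputs must be aligned on subjects and contain no
    missing values (run :func:`impute_and_filter` first).
    """
    Xf, Yf = _feature_frame(X), _feature_frame(Y)
    if len(Xf) != len(Yf):
        raise ValueError("blocks must have the same number of subjects")
    if Xf.isna().any().any() or Yf.isna().any().any():
        raise ValueError("missing values present; impute first")
    n = len(Xf)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    Zx = _standardize(Xf.to_numpy(), list(Xf.columns))
    Zy = _standardize(Yf.to_numpy(), list(Yf.columns))
    R = Zx.T @ Zy / (n - 1)
    return pd.DataFrame(R, index=Xf.columns, columns=Yf.columns)


def svd_saliences(R: np.ndarray):
    """SVD of the cross-correlation matrix with a deterministic sign.

    Returns ``(d, U, V)`` with ``R = U diag(d) Vᵀ``, singular values sorted
    descending, and the sign of each U column fixed so its largest-magnitude
    element is positive (the paired V column flips with it).
    """
    R = np.asarray(R, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("cross-correlation matrix has non-finite entries")
    U, d, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    for i in range(U.shape[1]):
        j = np.argmax(np.abs(U[:, i]))
        if U[j, i] < 0:
            U[:, i] = -U[:, i]
            V[:, i] = -V[:, i]
    return d, U, V


def _batched_singular_values(Zx: np.ndarray, Zy_batch: np.ndarray, n: int) -> np.ndarray:
    """Singular values of Zxᵀ Zy_b/(n−1) for a stack of permuted Y blocks."""
    R = np.einsum("np,bnq->bpq", Zx, Zy_batch) / (n - 1)
    return np.linalg.svd(R, compute_uv=False)


@dataclass
class LatentProjection:
    """Per-subject latent scores for one LV with group-mean bootstrap CIs."""

    lv: int
    behavior_scores: pd.Series
    brain_scores: pd.Series
    group_means: pd.DataFrame       # rows: group; cols: behavior, brain
    group_ci: pd.DataFrame          # rows: group; cols: lo/hi per side


class BehavioralPLSC:
    """PLSC model of the covariance between a behavior and a brain block.

    Parameters
    ----------
    behavior, brain
        Subject × feature tables aligned on subjects.  Columns named
        ``subject_id``/``group`` are treated as metadata; all other columns
        must be numeric and complete.
    groups
        Optional per-subject group labels; defaults to the ``group`` column
        of either table when present.
    """

    def __init__(self, behavior: pd.DataFrame, brain: pd.DataFrame, groups=None):
        Xf, Yf = _feature_frame(behavior), _feature_frame(brain)
        if len(Xf) != len(Yf):
            raise ValueError("behavior and brain blocks differ in subject count")
        if "subject_id" in behavior.columns and "subject_id" in brain.columns:
            if not behavior["subject_id"].reset_index(drop=True).equals(
                brain["subject_id"].reset_index(drop=True)
            ):
                raise ValueError("subject_id columns do not align")
        if groups is None:
            for t in (behavior, brain):
                if "group" in t.columns:
                    groups = t["group"].to_numpy()
                    break
        self.groups = None if groups is None else np.asarray(groups)
        self.behavior_names = list(Xf.columns)
        self.region_names = list(Yf.columns)
        self.n_subjects = len(Xf)
        self.Zx = _standardize(Xf.to_numpy(), self.behavior_names)
        self.Zy = _standardize(Yf.to_numpy(), self.region_names)

    @classmethod
    def from_tables(
        cls,
        behavior: pd.DataFrame,
        brain: pd.DataFrame,
        max_missing_per_group: int = 2,
    ) -> "BehavioralPLSC":
        """Build a model after group-wise imputation of the brain block."""
        brain = impute_and_filter(brain, max_missing_per_group=max_missing_per_group)
        return cls(behavior, brain)

    @property
    def cross_corr(self) -> pd.DataFrame:
        R = self.Zx.T @ self.Zy / (self.n_subjects - 1)
        return pd.DataFrame(R, index=self.behavior_names, columns=self.region_names)

    def fit(
        self,
        n_perm: int = 10_000,
        n_boot: int = 10_000,
        seed: int | None = None,
        chunk: int = 2_000,
    ) -> "PLSCResults":
        """Decompose, permute and bootstrap; return a :class:`PLSCResults`.

        ``n_perm`` row permutations of the brain block build the null
        distribution of singular values; ``n_boot`` subject resamples give
        the bootstrap standard errors behind the bootstrap ratios.  Either
        can be set to 0 to skip that inference step.
        """
        rng = np.random.default_rng(seed)
        R = self.Zx.T @ self.Zy / (self.n_subjects - 1)
        d, U, V = svd_saliences(R)

        perm_p = perm_cutoff = None
        inertia_p = None
        null_d = None
        if n_perm:
            null_d = self._permuted_singular_values(n_perm, rng, chunk)
            ge = (null_d >= d[np.newaxis, :]).sum(axis=0)
            perm_p = (ge + 1) / (n_perm + 1)
            perm_cutoff = np.percentile(null_d, 95, axis=0)
            null_inertia = (null_d**2).sum(axis=1)
            inertia_p = ((null_inertia >= (d**2).sum()).sum() + 1) / (n_perm + 1)

        br_x = br_y = None
        if n_boot:
            br_x, br_y = self._bootstrap_ratios(U, V, n_boot, rng, chunk)

        return PLSCResults(
            model=self,
            singular_values=d,
            behavior_saliences=pd.DataFrame(
                U, index=self.behavior_names,
                columns=[f"LV{i+1}" for i in range(U.shape[1])],
            ),
            brain_saliences=pd.DataFrame(
                V, index=self.region_names,
                columns=[f"LV{i+1}" for i in range(V.shape[1])],
            ),
            perm_p=perm_p,
            perm_cutoff=perm_cutoff,
            inertia_p=inertia_p,
            null_singular_values=null_d,
            boot_ratio_behavior=br_x,
            boot_ratio_brain=br_y,
            n_perm=n_perm,
            n_boot=n_boot,
        )

    # -- permutation ----------------------------------------------------
    def _permuted_singular_values(self, n_perm, rng, chunk) -> np.ndarray:
        n = self.n_subjects
        out = []
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            perms = np.array([rng.permutation(n) for _ in range(b)])
            out.append(_batched_singular_values(self.Zx, self.Zy[perms], n))
            done += b
        return np.concatenate(out, axis=0)

    # -- bootstrap ------------------------------------------------------
    def _bootstrap_ratios(self, U, V, n_boot, rng, chunk):
        n = self.n_subjects
        k = U.shape[1]
        p, q = len(self.behavior_names), len(self.region_names)
        # running sums for per-feature, per-LV SD of sign-aligned saliences
        sx = np.zeros((p, k)); sx2 = np.zeros((p, k))
        sy = np.zeros((q, k)); sy2 = np.zeros((q, k))
        redraws = 0
        done = 0
        while done < n_boot:
            b = min(chunk, n_boot - done)
            idx = rng.integers(0, n, size=(b, n))
            # redraw replicates containing a zero-variance column (capped)
            for _ in range(100):
                Xb = self.Zx[idx]
                Yb = self.Zy[idx]
                bad = (Xb.std(axis=1, ddof=1) == 0).any(axis=1) | (
                    Yb.std(axis=1, ddof=1) == 0
                ).any(axis=1)
                if not bad.any():
                    break
                redraws += int(bad.sum())
                idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
            else:
                raise RuntimeError("bootstrap redraw cap exceeded (degenerate data)")
            Zxb = (Xb - Xb.mean(axis=1, keepdims=True)) / Xb.std(axis=1, ddof=1, keepdims=True)
            Zyb = (Yb - Yb.mean(axis=1, keepdims=True)) / Yb.std(axis=1, ddof=1, keepdims=True)
            Rb = np.einsum("bnp,bnq->bpq", Zxb, Zyb) / (n - 1)
            Ub, _, Vtb = np.linalg.svd(Rb, full_matrices=False)
            Vb = np.swapaxes(Vtb, 1, 2)
            # sign-align each LV to the original via the combined dot product
            dots = np.einsum("bpk,pk->bk", Ub, U) + np.einsum("bqk,qk->bk", Vb, V)
            signs = np.where(dots < 0, -1.0, 1.0)
            Ub *= signs[:, np.newaxis, :]
            Vb *= signs[:, np.newaxis, :]
            sx += Ub.sum(axis=0); sx2 += (Ub**2).sum(axis=0)
            sy += Vb.sum(axis=0); sy2 += (Vb**2).sum(axis=0)
            done += b
        se_x = np.sqrt(np.maximum(sx2 - sx**2 / n_boot, 0.0) / (n_boot - 1))
        se_y = np.sqrt(np.maximum(sy2 - sy**2 / n_boot, 0.0) / (n_boot - 1))
        with np.errstate(divide="ignore", invalid="ignore"):
            br_x = U / se_x
            br_y = V / se_y
        cols = [f"LV{i+1}" for i in range(k)]
        self._bootstrap_redraws = redraws
        return (
            pd.DataFrame(br_x, index=self.behavior_names, columns=cols),
            pd.DataFrame(br_y, index=self.region_names, columns=cols),
        )


@dataclass
class PLSCResults:
    """Fitted PLSC decomposition with permutation and bootstrap inference.

    Attributes
    ----------
    singular_values
        δᵢ, the cross-block covariance captured per LV, descending.
    behavior_saliences, brain_saliences
        Columns of U and V; orthonormal feature weights per LV.
    perm_p
        Per-LV add-one permutation p-values ((k+1)/(n_perm+1)).
    perm_cutoff
        95th percentile of each LV's permutation-null singular values;
        an LV is flagged significant when its δ exceeds this cutoff.
    inertia_p
        Omnibus permutation p-value on the inertia Σδ².
    boot_ratio_behavior, boot_ratio_brain
        Bootstrap ratios; |BR| > 2 (strict) flags a reliable feature.
    """

    model: BehavioralPLSC
    singular_values: np.ndarray
    behavior_saliences: pd.DataFrame
    brain_saliences: pd.DataFrame
    perm_p: np.ndarray | None = None
    perm_cutoff: np.ndarray | None = None
    inertia_p: float | None = None
    null_singular_values: np.ndarray | None = field(default=None, repr=False)
    boot_ratio_behavior: pd.DataFrame | None = None
    boot_ratio_brain: pd.DataFrame | None = None
    n_perm: int = 0
    n_boot: int = 0

    @property
    def variance_explained(self) -> np.ndarray:
        d2 = self.singular_values**2
        return d2 / d2.sum()

    @property
    def inertia(self) -> float:
        """Σδᵢ² — the squared Frobenius norm of the cross-correlation."""
        return float((self.singular_values**2).sum())

    @property
    def significant(self) -> np.ndarray | None:
        """LVs whose singular value exceeds the 95th-percentile null cutoff."""
        if self.perm_cutoff is None:
            return None
        return self.singular_values > self.perm_cutoff

    def reliable_features(self, lv: int = 1, side: str = "behavior", threshold: float = 2.0):
        """Feature names with |BR| strictly above ``threshold`` on ``lv``."""
        br = self.boot_ratio_behavior if side == "behavior" else self.boot_ratio_brain
        if br is None:
            raise ValueError("bootstrap ratios were not computed")
        col = br[f"LV{lv}"]
        return list(col.index[np.abs(col) > threshold])

    def scores(self, lv: int = 1) -> pd.DataFrame:
        """Per-subject latent scores (standardized block · salience)."""
        i = lv - 1
        if not 0 <= i < len(self.singular_values):
            raise IndexError(f"LV {lv} out of range")
        m = self.model
        out = pd.DataFrame(
            {
                "behavior": m.Zx @ self.behavior_saliences.iloc[:, i].to_numpy(),
                "brain": m.Zy @ self.brain_saliences.iloc[:, i].to_numpy(),
            }
        )
        if m.groups is not None:
            out["group"] = m.groups
        return out

    def latent_projection(self, lv: int = 1, n_boot: int = 2_000, seed: int | None = None) -> LatentProjection:
        """Group means of the LV scores with percentile-bootstrap 95% CIs."""
        sc = self.scores(lv)
        if "group" not in sc.columns:
            raise ValueError("model has no group labels")
        rng = np.random.default_rng(seed)
        means = sc.groupby("group", observed=True)[["behavior", "brain"]].mean()
        rows = {}
        for g, sub in sc.groupby("group", observed=True):
            vals = sub[["behavior", "brain"]].to_numpy()
            idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
            boot_means = vals[idx].mean(axis=1)
            lo, hi = np.percentile(boot_means, [2.5, 97.5], axis=0)
            rows[g] = {
                "behavior_lo": lo[0], "behavior_hi": hi[0],
                "brain_lo": lo[1], "brain_hi": hi[1],
            }
        ci = pd.DataFrame(rows).T
        return LatentProjection(lv=lv, behavior_scores=sc["behavior"],
                                brain_scores=sc["brain"], group_means=means,
                                group_ci=ci)

    def plot_scores(self, lv: int = 1, n_boot: int = 2_000, seed: int | None = None, ax=None):
        """Scatter of subject latent scores with group means and 95% CI boxes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sc = self.scores(lv)
        if "group" in sc.columns:
            proj = self.latent_projection(lv, n_boot=n_boot, seed=seed)
            for g, sub in sc.groupby("group", observed=True):
                pts = ax.scatter(sub["behavior"], sub["brain"], label=str(g), alpha=0.7)
                color = pts.get_facecolor()[0]
                m = proj.group_means.loc[g]
                ci = proj.group_ci.loc[g]
                ax.scatter([m["behavior"]], [m["brain"]], marker="^", s=90, color=color)
                ax.add_patch(plt.Rectangle(
                    (ci["behavior_lo"], ci["brain_lo"]),
                    ci["behavior_hi"] - ci["behavior_lo"],
                    ci["brain_hi"] - ci["brain_lo"],
                    fill=False, linestyle=":", edgecolor=color,
                ))
            ax.legend(title="group")
        else:
            ax.scatter(sc["behavior"], sc["brain"], alpha=0.7)
        ax.set_xlabel(f"behavior LV{lv} score")
        ax.set_ylabel(f"brain LV{lv} score")
        return ax

    def summary(self) -> str:
        lines = [
            "Behavioral PLSC results",
            "=======================",
            f"subjects: {self.model.n_subjects}   "
            f"behaviors: {len(self.behavior_saliences)}   "
            f"regions: {len(self.brain_saliences)}",
            f"inertia (sum of squared singular values): {self.inertia:.4f}"
            + (f"   p = {self.inertia_p:.4g}" if self.inertia_p is not None else ""),
            "",
            f"{'LV':>4} {'delta':>10} {'var expl %':>11} "
            + (f"{'perm p':>10} {'sig':>4}" if self.perm_p is not None else ""),
        ]
        ve = self.variance_explained
        for i, d in enumerate(self.singular_values):
            row = f"{i+1:>4} {d:>10.4f} {100*ve[i]:>11.1f} "
            if self.perm_p is not None:
                row += f"{self.perm_p[i]:>10.4g} {'*' if self.significant[i] else '':>4}"
            lines.append(row)
        if self.boot_ratio_behavior is not None:
            lines += ["", "LV1 reliable features (|BR| > 2):",
                      f"  behavior: {self.reliable_features(1, 'behavior')}",
                      f"  brain:    {self.reliable_features(1, 'brain')}"]
        return "\n".join(lines)
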