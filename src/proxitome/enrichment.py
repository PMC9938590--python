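"""Replicate-level differential protein-abundance statistics.

The processing chain for one label-free LC-MS/MS experiment is fixed:

1. log2-transform raw intensities (missing cells stay missing);
2. normalize each sample to a common mean (subtract the per-sample mean of
   present values, add back the grand mean so the matrix keeps an
   interpretable log2-intensity scale);
3. impute missing cells from a downshifted normal distribution — mean
   ``mu - downshift*sigma`` and SD ``width_factor*sigma`` of the cell's
   scope (its sample column by default), the standard treatment of
   intensity-dependent (MNAR) dropout in label-free proteomics;
4. per protein, a heteroscedastic (Welch) two-sample t-test of bait vs
   reference samples, with the Welch–Satterthwaite degrees of freedom.

A protein is called *enriched* at level alpha when ``p < alpha`` and its
log2 fold change (bait minus reference) is positive: the workflow looks
for proteins biotinylated above background, so enrichment is
one-directional even though both tails are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceMatrix
from .errors import ConfigurationError, ValidationError

VALID_BAITS = ("nt_kdm5", "ct_kdm5")
VALID_REFERENCES = ("control", "turboid", "dcas9")


@dataclass(frozen=True)
class ComparisonSpec:
    """One bait-vs-reference comparison within one experiment batch."""

    bait: str
    reference: str
    experiment: str
    alpha_volcano: float = 0.05
    alpha_hci: float = 0.1

    def __post_init__(self) -> None:
        if self.bait == self.reference:
            raise ConfigurationError("bait and reference conditions must differ")
        if not (0 < self.alpha_volcano < 1) or not (0 < self.alpha_hci < 1):
            raise ConfigurationError(
                f"significance levels must lie in (0, 1), got "
                f"alpha_volcano={self.alpha_volcano}, alpha_hci={self.alpha_hci}"
            )

    @property
    def slot(self) -> str:
        """Canonical name, e.g. ``nt_kdm5_vs_control_exp1``."""
        return f"{self.bait}_vs_{self.reference}_{self.experiment}"


@dataclass(frozen=True)
class ImputationParams:
    """Downshifted-normal imputation parameters.

    ``downshift`` is the number of scope SDs subtracted from the scope mean
    (2.0 mirrors the standard low-abundance assumption); ``width_factor``
    scales the imputation spread relative to the scope SD (0.3, the common
    Perseus-style convention — imputing at the full observed SD inflates the
    variance of largely-missing proteins). Scope ``per_sample`` uses each
    sample column's own mean/SD; ``global`` uses the whole matrix.
    """

    downshift: float = 2.0
    width_factor: float = 0.3
    scope: str = "per_sample"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.downshift < 0:
            raise ConfigurationError("downshift must be >= 0")
        if self.width_factor <= 0:
            raise ConfigurationError("width_factor must be > 0")
        if self.scope not in ("per_sample", "global"):
            raise ConfigurationError(f"unknown imputation scope {self.scope!r}")


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def log2_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map present cells x -> log2(x); missing cells stay missing."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return pd.DataFrame(np.log2(matrix.to_numpy(dtype=float)),
                            index=matrix.index, columns=matrix.columns)


def normalize_by_sample_mean(log2_matrix: pd.DataFrame) -> pd.DataFrame:
    """Equalize per-sample means, preserving the grand log2-intensity scale.

    Each sample column is shifted so its mean over present values equals
    the grand mean of all present values in the matrix.
    """
    col_present = log2_matrix.notna().sum(axis=0)
    empty = list(col_present.index[col_present == 0])
    if empty:
        raise ValidationError(f"samples with no present values: {empty}")
    col_means = log2_matrix.mean(axis=0, skipna=True)
    grand = float(np.nanmean(log2_matrix.to_numpy(dtype=float)))
    return log2_matrix.sub(col_means, axis=1) + grand


def impute_missing(normalized: pd.DataFrame, params: ImputationParams
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill missing cells from a downshifted normal; return (matrix, mask).

    The mask is True where a cell was imputed. Present values are never
    altered. Draws come from one generator seeded with ``params.seed``,
    consumed column by column in column order, so identical inputs and
    parameters reproduce identical imputed values.
    """
    rng = np.random.default_rng(params.seed)
    out = normalized.copy()
    mask = normalized.isna()
    if params.scope == "global":
        present = normalized.to_numpy(dtype=float)
        present = present[~np.isnan(present)]
        if present.size < 2:
            raise ValidationError("global scope needs >=2 present values")
        mu, sd = float(present.mean()), float(present.std(ddof=1))
    for col in normalized.columns:
        col_mask = mask[col]
        n_miss = int(col_mask.sum())
        if params.scope == "per_sample":
            present = normalized[col].dropna()
            if len(present) < 2:
                raise ValidationError(
                    f"sample {col!r} has {len(present)} present values; "
                    "need >=2 to estimate imputation parameters"
                )
            mu, sd = float(present.mean()), float(present.std(ddof=1))
        if n_miss:
            draws = rng.normal(mu - params.downshift * sd,
                               params.width_factor * sd, size=n_miss)
            out.loc[col_mask, col] = draws
    return out, mask


def _welch_arrays(x: np.ndarray, y: np.ndarray, axis: int = -1
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t, df and two-sided p along ``axis``."""
    nx, ny = x.shape[axis], y.shape[axis]
    mx, my = x.mean(axis=axis), y.mean(axis=axis)
    vx, vy = x.var(axis=axis, ddof=1), y.var(axis=axis, ddof=1)
    sex, sey = vx / nx, vy / ny
    se2 = sex + sey
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2 ** 2 / (sex ** 2 / (nx - 1) + sey ** 2 / (ny - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate conventions: both groups constant
    zero = se2 == 0
    if np.any(zero):
        equal = zero & (mx == my)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        df = np.where(zero, float(nx + ny - 2), df)
        unequal = zero & (mx != my)
        if np.any(unequal):
            warnings.warn(
                "groups with zero variance and unequal means: p set to 0",
                RuntimeWarning, stacklevel=3,
            )
            t = np.where(unequal, np.sign(mx - my) * np.inf, t)
            p = np.where(unequal, 0.0, p)
    return t, df, p


def welch_ttest(x, y) -> WelchResult:
    """Two-sided heteroscedastic (Welch) t-test for two samples.

    Returns the t statistic, Welch–Satterthwaite degrees of freedom and the
    two-sided p-value ``2 * P(T_df >= |t|)``. Each group needs >= 2 values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) < 2 or len(y) < 2:
        raise ValidationError("welch_ttest needs two 1-D groups of >=2 values")
    t, df, p = _welch_arrays(x[None, :], y[None, :])
    return WelchResult(float(t[0]), float(df[0]), float(p[0]))


@dataclass
class PreparedExperiment:
    """One experiment's matrix after the fixed transform/normalize/impute chain."""

    complete: pd.DataFrame          # log2 scale, no missing cells
    imputed_mask: pd.DataFrame      # True where a cell was imputed
    metadata: pd.DataFrame
    dropped_proteins: tuple[str, ...] = field(default_factory=tuple)
    params: ImputationParams | None = None


def prepare_experiment(matrix: AbundanceMatrix, experiment: str,
                       params: ImputationParams) -> PreparedExperiment:
    """Run transform -> normalize -> impute on one experiment's samples.

    Proteins with no measurement in any sample of the experiment were not
    identified in that MS run; they are dropped here (and surface as
    ``not_tested`` in downstream calls) rather than being wholly invented
    by imputation.
    """
    sub = matrix.subset_experiment(experiment)
    all_missing = sub.values.isna().all(axis=1)
    dropped = tuple(sub.values.index[all_missing])
    values = sub.values.loc[~all_missing]
    log2 = log2_transform(values)
    normalized = normalize_by_sample_mean(log2)
    complete, mask = impute_missing(normalized, params)
    return PreparedExperiment(complete=complete, imputed_mask=mask,
                              metadata=sub.metadata, dropped_proteins=dropped,
                              params=params)


RESULT_COLUMNS = ("log2fc", "t", "df", "pvalue", "qvalue", "n_obs_bait",
                  "n_obs_ref", "enriched_05", "enriched_10", "excluded_reason")


def run_comparison(complete: pd.DataFrame, spec: ComparisonSpec,
                   imputed_mask: pd.DataFrame, metadata: pd.DataFrame,
                   min_obs_bait: int = 1) -> pd.DataFrame:
    """Volcano table for one bait-vs-reference comparison.

    ``complete`` is a fully imputed log2 matrix and ``imputed_mask`` marks
    the imputed cells; both come from :func:`prepare_experiment`.
    A protein is testable only if it has at least ``min_obs_bait``
    non-imputed measurements in the bait group — enrichment driven purely by
    imputed noise is meaningless. Benjamini–Hochberg q-values are reported
    as an audit column; the filtering workflow itself uses raw p-values.
    """
    meta = metadata.loc[list(complete.columns)]
    for cond in (spec.bait, spec.reference):
        if not (meta["condition"] == cond).any():
            raise ValidationError(
                f"condition {cond!r} absent from experiment {spec.experiment!r}"
            )
    bait_samples = list(meta.index[(meta["condition"] == spec.bait)
                                   & (meta["experiment"] == spec.experiment)])
    ref_samples = list(meta.index[(meta["condition"] == spec.reference)
                                  & (meta["experiment"] == spec.experiment)])
    if len(bait_samples) < 2 or len(ref_samples) < 2:
        raise ValidationError(
            f"comparison {spec.slot}: need >=2 samples per group, got "
            f"{len(bait_samples)} bait / {len(ref_samples)} reference"
        )
    X = complete[bait_samples].to_numpy(dtype=float)
    Y = complete[ref_samples].to_numpy(dtype=float)
    n_obs_bait = (~imputed_mask[bait_samples]).sum(axis=1).to_numpy()
    n_obs_ref = (~imputed_mask[ref_samples]).sum(axis=1).to_numpy()

    t, df, p = _welch_arrays(X, Y, axis=1)
    log2fc = X.mean(axis=1) - Y.mean(axis=1)

    excluded = n_obs_bait < min_obs_bait
    reason = np.where(
        excluded,
        np.where(n_obs_bait + n_obs_ref == 0, "all_missing", "no_observed_bait"),
        "",
    )
    t = np.where(excluded, np.nan, t)
    df = np.where(excluded, np.nan, df)
    p = np.where(excluded, np.nan, p)
    log2fc = np.where(excluded, np.nan, log2fc)

    q = np.full_like(p, np.nan)
    tested = ~excluded
    if tested.any():
        q[tested] = stats.false_discovery_control(p[tested], method="bh")

    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "pvalue": p,
            "qvalue": q,
            "n_obs_bait": n_obs_bait,
            "n_obs_ref": n_obs_ref,
            "enriched_05": tested & (p < spec.alpha_volcano) & (log2fc > 0),
            "enriched_10": tested & (p < spec.alpha_hci) & (log2fc > 0),
            "excluded_reason": reason,
        },
        index=complete.index,
    )
    result.index.name = "protein_id"
    return result


def run_experiment_comparisons(matrix: AbundanceMatrix,
                               specs: list[ComparisonSpec],
                               params: ImputationParams,
                               min_obs_bait: int = 1
                               ) -> dict[str, pd.DataFrame]:
    """Prepare each experiment once and run all its comparisons.

    Comparisons from the same experiment share one processed (normalized +
    imputed) matrix, mirroring a single per-experiment export.
    """
    results: dict[str, pd.DataFrame] = {}
    for experiment in sorted({s.experiment for s in specs}):
        prepared = prepare_experiment(matrix, experiment, params)
        for spec in specs:
            if spec.experiment != experiment:
                continue
            results[spec.slot] = run_comparison(
                prepared.complete, spec, prepared.imputed_mask,
                prepared.metadata, min_obs_bait=min_obs_bait,
            )
    return results
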