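"""The consonants-in-noise preliteracy score: a two-block hierarchical OLS.

Block 1 holds the demographic covariates (sex, age, non-verbal IQ); block
2 adds the nine neural-coding predictors (four transient-peak latencies,
four first-formant harmonic amplitudes, and response stability).  The
model reports the variance explained by each block (R-squared, its
increment Delta R-squared, and the F-change test), standardized
coefficients, and per-predictor collinearity tolerances.

A fitted model is frozen and *transferred*: applying it to a new cohort
uses the raw-scale training coefficients only, never a refit.  The
resulting per-child prediction is the "consonants-in-noise score", which
downstream analyses correlate with behavioral outcomes or feed to the
diagnostic classifier.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .metrics import METRIC_COLUMNS as NEURAL_COLUMNS

#: default block-1 (demographic) columns; sex is dummy-coded male=0, female=1
DEMOGRAPHIC_COLUMNS = ["sex", "age_months", "nonverbal_iq"]


@dataclass
class ScoreVector:
    """Frozen-model predictions ('consonants-in-noise scores') per child."""

    scores: pd.Series
    fit_hash: str
    refit_flag: bool = False
    missing_ids: tuple = ()   # children skipped for missing predictors


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    r_adjusted: float | None = None


class PreliteracyScoreModel:
    """Two-block hierarchical regression of a behavioral outcome.

    Parameters
    ----------
    data : DataFrame
        One row per child; must contain the outcome and all predictor
        columns.  Rows with any missing cell are dropped (listwise
        deletion) before fitting.
    outcome : str
        Name of the behavioral outcome column.
    block1, block2 : list of str
        Demographic and neural predictor column names.  Single-block
        variants (timing-only, spectral-only, stability-only) are just
        this model with a column subset — no separate code path.
    """

    def __init__(self, data: pd.DataFrame, outcome: str,
                 block1: list | None = None, block2: list | None = None):
        self.outcome = outcome
        self.block1 = list(block1 if block1 is not None else DEMOGRAPHIC_COLUMNS)
        self.block2 = list(block2 if block2 is not None else NEURAL_COLUMNS)
        cols = [outcome] + self.block1 + self.block2
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"missing columns: {missing}")
        full = data[cols]
        self.n_dropped = int(full.isna().any(axis=1).sum())
        self.data = full.dropna()
        n, k = len(self.data), len(self.block1) + len(self.block2)
        if n <= k + 1:
            raise ValueError(
                f"n = {n} too small for {k} predictors (need n > k + 1)"
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, **kwargs):
        return cls(data, outcome, **kwargs)

    def fit(self) -> "PreliteracyScoreResults":
        y = self.data[self.outcome].to_numpy(dtype=float)
        x1 = self.data[self.block1].to_numpy(dtype=float)
        x2 = self.data[self.block1 + self.block2].to_numpy(dtype=float)

        rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), x2]))
        if rank < x2.shape[1] + 1:
            corr = pd.DataFrame(x2, columns=self.block1 + self.block2).corr()
            pairs = [
                (a, b) for a in corr.columns for b in corr.columns
                if a < b and abs(corr.loc[a, b]) > 1 - 1e-10
            ]
            raise ValueError(f"rank-deficient design; collinear columns: {pairs}")

        fit1 = sm.OLS(y, sm.add_constant(x1)).fit()
        fit2 = sm.OLS(y, sm.add_constant(x2)).fit()

        n = len(y)
        k1, k2 = len(self.block1), len(self.block2)
        r2_1, r2_t = float(fit1.rsquared), float(fit2.rsquared)
        delta = r2_t - r2_1
        df2 = n - k1 - k2 - 1
        resid_ms = (1.0 - r2_t) / df2
        f_change = (delta / k2) / resid_ms if resid_ms > 0 else np.inf
        p_change = float(stats.f.sf(f_change, k2, df2))

        names = self.block1 + self.block2
        params = pd.Series(fit2.params, index=["intercept"] + names)
        # standardized betas from the fitting sample's z-scored columns
        sd_x = self.data[names].std(ddof=1).to_numpy()
        sd_y = float(np.std(y, ddof=1))
        std_params = pd.Series(fit2.params[1:] * sd_x / sd_y, index=names)

        tol = {}
        for j, name in enumerate(names):
            others = np.delete(x2, j, axis=1)
            aux = sm.OLS(x2[:, j], sm.add_constant(others)).fit()
            tol[name] = float(1.0 - aux.rsquared)

        return PreliteracyScoreResults(
            model=self, params=params, std_params=std_params,
            r2_block1=r2_1, r2_total=r2_t, delta_r2=delta,
            f_change=float(f_change), df_change=(k2, df2),
            p_change=p_change, tolerance=pd.Series(tol),
            f_block1=float(fit1.fvalue), p_block1=float(fit1.f_pvalue),
            f_total=float(fit2.fvalue), p_total=float(fit2.f_pvalue),
            n=n, fitted_values=pd.Series(fit2.fittedvalues,
                                         index=self.data.index),
        )


@dataclass
class PreliteracyScoreResults:
    """Frozen hierarchical fit: coefficients, variance decomposition, diagnostics."""

    model: PreliteracyScoreModel | None
    params: pd.Series          # raw-scale, with intercept
    std_params: pd.Series      # standardized betas (no intercept)
    r2_block1: float
    r2_total: float
    delta_r2: float
    f_change: float
    df_change: tuple
    p_change: float
    tolerance: pd.Series
    f_block1: float
    p_block1: float
    f_total: float
    p_total: float
    n: int
    fitted_values: pd.Series | None = None

    @property
    def predictor_names(self) -> list:
        return [name for name in self.params.index if name != "intercept"]

    def fit_hash(self) -> str:
        payload = json.dumps(
            {"params": self.params.round(12).to_dict(), "n": self.n},
            sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def predict(self, data: pd.DataFrame) -> ScoreVector:
        """Frozen-coefficient transfer to a (possibly new) cohort.

        Uses the raw-scale training coefficients only; a child with any
        missing predictor receives no score and is flagged.  The outcome
        column is not required.
        """
        names = self.predictor_names
        missing_cols = [c for c in names if c not in data.columns]
        if missing_cols:
            raise KeyError(f"design is missing predictor columns: {missing_cols}")
        x = data[names].astype(float)
        ok = ~x.isna().any(axis=1)
        scores = (self.params["intercept"]
                  + x[ok].to_numpy() @ self.params[names].to_numpy())
        return ScoreVector(
            scores=pd.Series(scores, index=data.index[ok], name="cin_score"),
            fit_hash=self.fit_hash(), refit_flag=False,
            missing_ids=tuple(data.index[~ok]),
        )

    def summary(self) -> str:
        lines = [
            "Consonants-in-noise score: hierarchical regression",
            "=" * 54,
            f"n = {self.n}",
            f"Step 1 (demographics)   R2 = {self.r2_block1:.3f}  "
            f"F = {self.f_block1:.3f} (p = {self.p_block1:.3f})",
            f"Step 2 (+ neural)  total R2 = {self.r2_total:.3f}  "
            f"F = {self.f_total:.3f} (p = {self.p_total:.3f})",
            f"Delta R2 = {self.delta_r2:.3f}  "
            f"F[{self.df_change[0]},{self.df_change[1]}] = {self.f_change:.3f} "
            f"(p = {self.p_change:.3f})",
            "-" * 54,
            f"{'predictor':<18}{'b':>10}{'beta':>10}{'tolerance':>12}",
        ]
        lines.append(f"{'intercept':<18}{self.params['intercept']:>10.3f}")
        for name in self.predictor_names:
            lines.append(
                f"{name:<18}{self.params[name]:>10.3f}"
                f"{self.std_params[name]:>10.3f}{self.tolerance[name]:>12.3f}"
            )
        return "\n".join(lines)

    def to_json(self, path=None) -> str:
        payload = {
            "outcome": self.model.outcome if self.model else None,
            "params": self.params.to_dict(),
            "std_params": self.std_params.to_dict(),
            "r2_block1": self.r2_block1, "r2_total": self.r2_total,
            "delta_r2": self.delta_r2, "f_change": self.f_change,
            "df_change": list(self.df_change), "p_change": self.p_change,
            "tolerance": self.tolerance.to_dict(), "n": self.n,
            "fit_hash": self.fit_hash(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PreliteracyScoreResults":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            model=None,
            params=pd.Series(payload["params"]),
            std_params=pd.Series(payload["std_params"]),
            r2_block1=payload["r2_block1"], r2_total=payload["r2_total"],
            delta_r2=payload["delta_r2"], f_change=payload["f_change"],
            df_change=tuple(payload["df_change"]), p_change=payload["p_change"],
            tolerance=pd.Series(payload["tolerance"]),
            f_block1=float("nan"), p_block1=float("nan"),
            f_total=float("nan"), p_total=float("nan"), n=payload["n"],
        )


def correlate(scores, outcome, reliability: float | None = None) -> CorrelationResult:
    """Pearson correlation of scores against a behavioral outcome.

    With a test-retest ``reliability`` given, also reports the
    disattenuated correlation r / sqrt(reliability) (correcting for the
    outcome's measurement unreliability only), capped at 1.
    """
    x = pd.Series(scores.scores if isinstance(scores, ScoreVector) else scores)
    y = pd.Series(outcome)
    joined = pd.concat([x, y], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 paired observations")
    a, b = joined.iloc[:, 0], joined.iloc[:, 1]
    if a.std(ddof=0) == 0 or b.std(ddof=0) == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(a, b)
    r_adj = None
    if reliability is not None:
        if not (0.0 < reliability <= 1.0):
            raise ValueError("reliability must be in (0, 1]")
        r_adj = float(np.sign(r) * min(abs(r) / np.sqrt(reliability), 1.0))
    return CorrelationResult(r=float(r), n=len(joined), p=float(p),
                             r_adjusted=r_adj)


def prediction_error_summary(actual, predicted) -> dict:
    """Median and range of |actual - predicted| over paired children."""
    joined = pd.concat([pd.Series(actual), pd.Series(predicted)],
                       axis=1, join="inner").dropna()
    err = (joined.iloc[:, 0] - joined.iloc[:, 1]).abs()
    return {"median": float(err.median()), "min": float(err.min()),
            "max": float(err.max()), "n": int(len(err))}


def cross_validate(data: pd.DataFrame, outcome: str, n_train: int = 20,
                   seed: int = 0, block1=None, block2=None):
    """Random-split cross-validation of the frozen score transfer.

    Refits the hierarchical model on ``n_train`` randomly chosen children
    and transfers the frozen coefficients to the holdout; returns
    (training results, holdout Pearson r).
    """
    n = len(data)
    if not (0 < n_train < n):
        raise ValueError(f"n_train must be in (0, {n}); empty holdout otherwise")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train = data.iloc[order[:n_train]]
    hold = data.iloc[order[n_train:]]
    results = PreliteracyScoreModel(train, outcome,
                                    block1=block1, block2=block2).fit()
    scores = results.predict(hold)
    cr = correlate(scores, hold[outcome])
    return results, cr.r
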