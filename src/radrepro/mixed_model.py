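"""Per-feature linear mixed model with a random subject intercept.

Model for feature value :math:`y_{ij}` of subject *i* under reconstruction
setting *j*:

.. math::

    y_{ij} = \\beta_0 + \\beta_{setting(j)} + \\beta_s\\,scanner_i
             + \\beta_v\\,voltage_i + \\beta_c\\,volume_i + b_i
             + \\varepsilon_{ij},

with :math:`b_i \\sim N(0, \\sigma_b^2)` and
:math:`\\varepsilon_{ij} \\sim N(0, \\sigma_e^2)` independent. The setting
enters as a categorical factor against a reference level, so each
non-reference setting gets one coefficient measuring its systematic shift
relative to the reference.

Estimation is REML via the profiled likelihood on the variance ratio
:math:`\\lambda = \\sigma_b^2/\\sigma_e^2`: for a single random intercept the
marginal covariance is block compound-symmetric, so each candidate
:math:`\\lambda` admits a closed-form GLS step and the REML criterion reduces
to a one-dimensional optimisation. Inference uses t statistics with the
between-within degrees-of-freedom convention: within-subject terms (setting
contrasts) get ``df = n_obs - n_subjects - n_within_terms``; between-subject
terms (scanner, voltage, volume) get ``df = n_subjects - n_between_terms - 1``.

On a balanced complete design each setting coefficient equals the mean over
subjects of (value at that setting minus value at the reference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import ReconstructionDesign
from .feature_table import FeatureTable
from .group_tests import fdr_adjust

__all__ = [
    "MixedModelSpec",
    "FeatureMixedModel",
    "FeatureMixedModelResults",
    "fit_feature_mixed_model",
    "batch_mixed_models",
]

logger = logging.getLogger(__name__)

_LOGLAM_BOUNDS = (-14.0, 14.0)


@dataclass(frozen=True)
class MixedModelSpec:
    """Which fixed effects enter the per-feature mixed model."""

    reference_setting: str | None = None  # default: the design's reference
    include_scanner: bool = True
    include_voltage: bool = True
    include_volume: bool = True
    log_volume: bool = False
    reml: bool = True


class FeatureMixedModel:
    """Random-intercept linear mixed model for one response vector.

    Parameters
    ----------
    endog
        Response values, one per (subject, setting) observation.
    subjects
        Subject identifier per observation (random-intercept grouping).
    setting
        Setting label per observation (categorical fixed effect).
    design
        Reconstruction design supplying the setting order and reference.
    between
        Optional frame of between-subject covariates, one row per
        observation (constant within subject). Categorical columns are dummy
        coded against their lexicographically first level.
    reference
        Reference setting label; defaults to ``design.reference_label``.
    """

    def __init__(
        self,
        endog: Sequence[float],
        subjects: Sequence[str],
        setting: Sequence[str],
        design: ReconstructionDesign,
        between: pd.DataFrame | None = None,
        reference: str | None = None,
        reml: bool = True,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float)
        subjects = np.asarray(subjects)
        setting = np.asarray(setting)
        n = self.endog.size
        if subjects.size != n or setting.size != n:
            raise ValueError("endog, subjects and setting must have equal length")
        self.design = design
        self.reference = reference or design.reference_label
        if self.reference not in design.setting_labels:
            raise ValueError(f"reference {self.reference!r} not in design")
        self.reml = reml

        uniq_subj, self.group_idx = np.unique(subjects, return_inverse=True)
        self.n_subjects = uniq_subj.size
        if self.n_subjects < 3:
            raise ValueError("need at least 3 subjects")
        present = [s for s in design.setting_labels if s in set(setting)]
        if len(present) < 2:
            raise ValueError("need at least 2 settings present")

        cols: list[np.ndarray] = [np.ones(n)]
        names: list[str] = ["Intercept"]
        kinds: list[str] = ["between"]  # intercept counted with between df
        for lab in present:
            if lab == self.reference:
                continue
            cols.append((setting == lab).astype(float))
            names.append(f"setting[{lab}]")
            kinds.append("within")
        if between is not None:
            for col in between.columns:
                series = between[col]
                if pd.api.types.is_numeric_dtype(series):
                    cols.append(series.to_numpy(dtype=float))
                    names.append(col)
                    kinds.append("between")
                else:
                    levels = sorted(series.astype(str).unique())
                    for lev in levels[1:]:
                        cols.append((series.astype(str) == lev).to_numpy(dtype=float))
                        names.append(f"{col}[{lev}]")
                        kinds.append("between")
        self.exog = np.column_stack(cols)
        self.term_names = names
        self.term_kinds = kinds
        rank = np.linalg.matrix_rank(self.exog)
        if rank < self.exog.shape[1]:
            collinear = self._collinear_terms()
            raise ValueError(
                f"design matrix rank deficient; collinear terms: {collinear}"
            )

    def _collinear_terms(self) -> list[str]:
        # identify columns whose removal restores full rank
        bad = []
        full = np.linalg.matrix_rank(self.exog)
        for j in range(self.exog.shape[1]):
            reduced = np.delete(self.exog, j, axis=1)
            if np.linalg.matrix_rank(reduced) == full:
                bad.append(self.term_names[j])
        return bad

    # ------------------------------------------------------------------ #
    def _vinv_apply(self, m: np.ndarray, lam: float, counts: np.ndarray) -> np.ndarray:
        """Apply the block compound-symmetry inverse (I + lam*J)^-1 per subject."""
        shrink = lam / (1.0 + lam * counts)
        sums = np.vstack(
            [
                np.bincount(self.group_idx, weights=m[:, k], minlength=self.n_subjects)
                for k in range(m.shape[1])
            ]
        ).T
        return m - shrink[self.group_idx, None] * sums[self.group_idx]

    def _profile(self, lam: float):
        """GLS step at fixed variance ratio; returns (crit, beta, XtVX, rss)."""
        y = self.endog
        X = self.exog
        n, p = X.shape
        counts = np.bincount(self.group_idx, minlength=self.n_subjects).astype(float)
        A = np.column_stack([X, y])
        W = self._vinv_apply(A, lam, counts)
        XtVX = X.T @ W[:, :p]
        XtVy = X.T @ W[:, p]
        ytVy = float(y @ W[:, p])
        beta = np.linalg.solve(XtVX, XtVy)
        rss = max(ytVy - float(XtVy @ beta), 1e-300)
        logdet_v = float(np.sum(np.log1p(lam * counts)))
        if self.reml:
            sign, logdet_x = np.linalg.slogdet(XtVX)
            crit = (n - p) * np.log(rss) + logdet_v + logdet_x
        else:
            crit = n * np.log(rss) + logdet_v
        return crit, beta, XtVX, rss

    def fit(self) -> "FeatureMixedModelResults":
        converged = True
        try:
            res = optimize.minimize_scalar(
                lambda ll: self._profile(np.exp(ll))[0],
                bounds=_LOGLAM_BOUNDS,
                method="bounded",
                options={"xatol": 1e-10},
            )
            loglam = float(res.x)
            lam = float(np.exp(loglam))
            crit_opt = float(res.fun)
            crit_zero = self._profile(0.0)[0]
            if crit_zero <= crit_opt:
                lam = 0.0
            if not res.success:
                converged = False
        except (np.linalg.LinAlgError, FloatingPointError):
            logger.warning("mixed model optimisation failed; falling back to lam=0")
            lam, converged = 0.0, False
        _, beta, XtVX, rss = self._profile(lam)
        n, p = self.exog.shape
        dof = (n - p) if self.reml else n
        sigma_e2 = rss / dof
        sigma_b2 = lam * sigma_e2
        cov_beta = sigma_e2 * np.linalg.inv(XtVX)
        se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))

        n_within = sum(k == "within" for k in self.term_kinds)
        n_between = sum(k == "between" for k in self.term_kinds) - 1  # excl. intercept
        df_within = max(n - self.n_subjects - n_within, 1)
        df_between = max(self.n_subjects - n_between - 1, 1)
        dfs = np.array(
            [df_within if k == "within" else df_between for k in self.term_kinds],
            dtype=float,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.where(beta == 0, 0.0, np.inf))
        pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)
        pvals = np.where(np.isfinite(tvals), pvals, 0.0)
        pvals = np.where((se == 0) & (beta == 0), 1.0, pvals)

        index = pd.Index(self.term_names, name="term")
        return FeatureMixedModelResults(
            model=self,
            params=pd.Series(beta, index=index),
            bse=pd.Series(se, index=index),
            tvalues=pd.Series(tvals, index=index),
            pvalues=pd.Series(pvals, index=index),
            df=pd.Series(dfs, index=index),
            var_subject=float(sigma_b2),
            var_residual=float(sigma_e2),
            converged=converged,
        )


@dataclass
class FeatureMixedModelResults:
    """Fitted per-feature mixed model: estimates, uncertainty, diagnostics."""

    model: FeatureMixedModel
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df: pd.Series
    var_subject: float
    var_residual: float
    converged: bool
    feature_name: str = ""

    @property
    def n_obs(self) -> int:
        return int(self.model.endog.size)

    @property
    def n_subjects(self) -> int:
        return int(self.model.n_subjects)

    @property
    def setting_terms(self) -> list[str]:
        return [t for t in self.params.index if t.startswith("setting[")]

    def setting_coefficients(self) -> dict[str, float]:
        """Mapping non-reference setting label -> fitted shift vs reference."""
        out = {}
        for t in self.setting_terms:
            out[t[len("setting[") : -1]] = float(self.params[t])
        return out

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2.0, self.df)
        lo = self.params - q * self.bse
        hi = self.params + q * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def to_frame(self) -> pd.DataFrame:
        """Long per-term frame (the machine-readable twin of the fit)."""
        return pd.DataFrame(
            {
                "feature": self.feature_name,
                "term": self.params.index,
                "estimate": self.params.to_numpy(),
                "se": self.bse.to_numpy(),
                "df": self.df.to_numpy(),
                "p_raw": self.pvalues.to_numpy(),
                "var_subject": self.var_subject,
                "var_residual": self.var_residual,
                "converged": self.converged,
            }
        )

    def summary(self) -> str:
        lines = [
            "Random-intercept mixed model"
            + (f" -- {self.feature_name}" if self.feature_name else ""),
            f"  n_obs={self.n_obs}  n_subjects={self.n_subjects}  "
            f"REML={self.model.reml}  converged={self.converged}",
            f"  var(subject)={self.var_subject:.6g}  var(residual)={self.var_residual:.6g}",
            f"  {'term':<24}{'estimate':>12}{'se':>12}{'t':>10}{'df':>8}{'p':>12}",
        ]
        for t in self.params.index:
            lines.append(
                f"  {t:<24}{self.params[t]:>12.5g}{self.bse[t]:>12.5g}"
                f"{self.tvalues[t]:>10.3f}{self.df[t]:>8.0f}{self.pvalues[t]:>12.4g}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------- #
def fit_feature_mixed_model(
    table: FeatureTable, feature: str, spec: MixedModelSpec | None = None
) -> FeatureMixedModelResults:
    """Fit the multivariable mixed model for one feature of a table.

    Fixed effects: setting (categorical vs the reference), scanner, tube
    voltage and tumour volume, per ``spec``. Volume is dropped automatically
    when the response feature is itself volume-like.
    """
    spec = spec or MixedModelSpec()
    desc = table.descriptor(feature)
    settings = list(table.design.setting_labels)
    mat, pids = table.feature_matrix(feature, settings)
    n_pat, n_set = mat.shape
    endog = mat.ravel()
    subjects = np.repeat(pids, n_set)
    setting = np.tile(settings, n_pat)

    between_cols: dict[str, object] = {}
    meta = table.metadata.loc[pids]
    if spec.include_scanner:
        between_cols["scanner"] = np.repeat(meta["scanner"].astype(str).to_numpy(), n_set)
    if spec.include_voltage:
        between_cols["voltage"] = np.repeat(
            meta["tube_voltage"].astype(str).to_numpy(), n_set
        )
    if spec.include_volume and not desc.is_volume_like:
        vol = meta["tumour_volume_cm3"].to_numpy(dtype=float)
        if spec.log_volume:
            vol = np.log(vol)
        between_cols["volume"] = np.repeat(vol, n_set)
    between = pd.DataFrame(between_cols) if between_cols else None
    # drop between-subject factors with a single level (uninformative)
    if between is not None:
        keep = [
            c
            for c in between.columns
            if pd.api.types.is_numeric_dtype(between[c])
            or between[c].astype(str).nunique() > 1
        ]
        between = between[keep] if keep else None

    model = FeatureMixedModel(
        endog,
        subjects,
        setting,
        table.design,
        between=between,
        reference=spec.reference_setting,
        reml=spec.reml,
    )
    res = model.fit()
    res.feature_name = feature
    return res


def batch_mixed_models(
    table: FeatureTable,
    spec: MixedModelSpec | None = None,
    features: Sequence[str] | None = None,
) -> tuple[list[FeatureMixedModelResults], pd.DataFrame]:
    """Fit the mixed model for every feature and FDR-adjust p values.

    Adjustment is applied per term family across features: all setting
    contrasts together, scanner terms together, voltage terms together and
    volume terms together, matching the reporting granularity of the
    per-family supplementary tables.

    Returns
    -------
    (fits, terms)
        ``fits`` is the list of per-feature results (failed features are
        skipped with a warning); ``terms`` is a long frame with columns
        ``feature, term, estimate, se, df, p_raw, p_fdr, var_subject,
        var_residual, converged``.
    """
    if features is None:
        features = table.feature_names
    fits: list[FeatureMixedModelResults] = []
    frames = []
    for name in features:
        try:
            res = fit_feature_mixed_model(table, name, spec)
        except (ValueError, KeyError, np.linalg.LinAlgError) as exc:
            logger.warning("mixed model failed for feature %s: %s", name, exc)
            continue
        fits.append(res)
        frames.append(res.to_frame())
    if not frames:
        return fits, pd.DataFrame(
            columns=[
                "feature", "term", "estimate", "se", "df", "p_raw", "p_fdr",
                "var_subject", "var_residual", "converged",
            ]
        )
    terms = pd.concat(frames, ignore_index=True)

    def family(term: str) -> str:
        if term.startswith("setting["):
            return "setting"
        if term.startswith("scanner["):
            return "scanner"
        if term.startswith("voltage["):
            return "voltage"
        if term == "volume":
            return "volume"
        return "intercept"

    terms["p_fdr"] = np.nan
    for fam, idx in terms.groupby(terms["term"].map(family)).groups.items():
        if fam == "intercept":
            terms.loc[idx, "p_fdr"] = terms.loc[idx, "p_raw"]
        else:
            terms.loc[idx, "p_fdr"] = fdr_adjust(terms.loc[idx, "p_raw"].to_numpy())
    return fits, terms
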