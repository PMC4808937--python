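"""Hypothesis tests on fitted models.

Three layers: per-coefficient and collective ("overall effect") Wald tests
— the collective test pools one covariate's four muscle-specific
coefficients into a 4-df chi-square; likelihood-ratio tests between nested
rungs of the model ladder; and a battery assembling the study's four
clinical null hypotheses (equality of arms, pain, clinical risk factors,
effect modification by the affected side).

Wald statistics use the asymptotic chi-square reference (no denominator
degrees of freedom).  Variance-component LRTs whose null lies on the
boundary of the parameter space are reported with the naive chi-square
p-value plus a clearly labelled 50:50 chi-square-mixture alternative.
No multiplicity correction is applied; p-values are raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import MUSCLES, ObservationTable
from .design import DesignSpec, build_design, default_design_spec, drop_terms
from .errors import NestingError, SpecError
from .estimation import FitOptions, FitResult, fit

_VARIANT_ORDER = {"model3": 0, "model4": 1, "model6": 2}


@dataclass(frozen=True)
class WaldResult:
    statistic: float
    df: int
    p_value: float
    contrast: str = ""

    def __str__(self):
        return f"Wald chi2({self.df}) = {self.statistic:.3f}, p = {self.p_value:.4g}  [{self.contrast}]"


@dataclass(frozen=True)
class LRTResult:
    delta_deviance: float
    df: int
    p_value: float
    null_variant: str = ""
    full_variant: str = ""
    mixture_p_value: float | None = None  # boundary-adjusted, variance-component nulls only

    def __str__(self):
        s = (
            f"LRT {self.null_variant} vs {self.full_variant}: "
            f"delta deviance = {self.delta_deviance:.3f} on {self.df} df, p = {self.p_value:.4g}"
        )
        if self.mixture_p_value is not None:
            s += f" (50:50 mixture p = {self.mixture_p_value:.4g})"
        return s


def contrast_for_labels(fit_result: FitResult, labels) -> np.ndarray:
    """Selection contrast: one row per named coefficient."""
    C = np.zeros((len(labels), len(fit_result.labels)))
    for r, lab in enumerate(labels):
        try:
            C[r, fit_result.labels.index(lab)] = 1.0
        except ValueError:
            raise SpecError(f"no coefficient labelled {lab!r} in this fit") from None
    return C


def collective_contrast(fit_result: FitResult, term: str) -> np.ndarray:
    """The 4-row contrast selecting one design term across all four muscles."""
    return contrast_for_labels(fit_result, [f"{m}.{term}" for m in MUSCLES])


def wald_test(fit_result: FitResult, contrast, description: str = "") -> WaldResult:
    """Wald chi-square test of C beta = 0.

    statistic = (C b)' (C Cov(b) C')^{-1} (C b), df = rank(C).  A
    rank-deficient contrast is reduced to its row space with a warning.
    """
    if isinstance(contrast, (list, tuple)) and contrast and isinstance(contrast[0], str):
        contrast = contrast_for_labels(fit_result, contrast)
    C = np.atleast_2d(np.asarray(contrast, dtype=float))
    if C.shape[1] != len(fit_result.labels):
        raise SpecError(f"contrast has {C.shape[1]} columns, fit has {len(fit_result.labels)}")
    df = int(np.linalg.matrix_rank(C))
    if df == 0:
        raise SpecError("contrast matrix is zero")
    if df < C.shape[0]:
        warnings.warn(
            f"contrast is rank deficient (rank {df} < {C.shape[0]} rows); df reduced",
            UserWarning,
            stacklevel=2,
        )
    Cb = C @ fit_result.params.beta
    S = C @ fit_result.beta_cov @ C.T
    stat = float(Cb @ np.linalg.pinv(S, rcond=1e-12) @ Cb)
    stat = max(stat, 0.0)
    return WaldResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        contrast=description or f"{C.shape[0]}-row contrast",
    )


def collective_wald(fit_result: FitResult, term: str) -> WaldResult:
    """Overall-effect test of one covariate on all four muscles (4 df)."""
    C = collective_contrast(fit_result, term)
    res = wald_test(fit_result, C, description=f"overall effect of {term}")
    return res


def _is_nested(null: FitResult, full: FitResult) -> bool:
    cols_ok = set(null.labels) <= set(full.labels)
    var_ok = _VARIANT_ORDER[null.variant] <= _VARIANT_ORDER[full.variant]
    return cols_ok and var_ok


def lrt(null: FitResult, full: FitResult) -> LRTResult:
    """Likelihood-ratio test of two nested fits on the same data.

    delta = deviance(null) - deviance(full), df the difference in free
    parameter counts, p from the upper chi-square tail.  A negative delta
    (optimizer noise) is clipped at zero with a warning.  When only
    variance components differ and the null puts them on the boundary, a
    50:50 chi-square mixture p-value (one-component boundary
    approximation) is attached as well.
    """
    if null.estimation != full.estimation:
        raise NestingError("fits use different estimation modes")
    fixed_differ = null.labels != full.labels
    if fixed_differ and null.estimation == "REML":
        raise NestingError(
            "REML likelihoods are not comparable across different fixed effects; refit with ML"
        )
    if not _is_nested(null, full):
        raise NestingError(
            f"{null.variant} ({len(null.labels)} columns) is not nested in "
            f"{full.variant} ({len(full.labels)} columns)"
        )
    if null.design is not None and full.design is not None:
        if null.design.n_obs != full.design.n_obs:
            raise NestingError("fits are not on the same data (different observation counts)")
    df = full.n_total_params - null.n_total_params
    if df <= 0:
        if null.n_total_params == full.n_total_params:
            return LRTResult(0.0, 0, 1.0, null.variant, full.variant) if np.isclose(
                null.deviance, full.deviance
            ) else _raise_same_size()
        raise NestingError("null model has more parameters than the full model")
    delta = null.deviance - full.deviance
    if delta < 0:
        warnings.warn(
            f"negative deviance change ({delta:.3g}) clipped to 0 (optimizer noise)",
            UserWarning,
            stacklevel=2,
        )
        delta = 0.0
    p = float(stats.chi2.sf(delta, df))
    mixture = None
    if not fixed_differ and null.variant != full.variant:
        # variance components on the boundary: 50:50 mixture of chi2(df) and chi2(df-1)
        lower = float(stats.chi2.sf(delta, df - 1)) if df > 1 else (1.0 if delta <= 0 else 0.0)
        mixture = 0.5 * p + 0.5 * lower
    return LRTResult(
        delta_deviance=float(delta),
        df=int(df),
        p_value=p,
        null_variant=null.variant,
        full_variant=full.variant,
        mixture_p_value=mixture,
    )


def _raise_same_size():
    raise NestingError("models have equal parameter counts but different deviances")


@dataclass
class BatteryReport:
    """Structured report of the clinical hypothesis battery."""

    rows: pd.DataFrame
    fits: dict = field(default_factory=dict, repr=False)

    def to_text(self) -> str:
        out = ["Clinical hypothesis battery", "=" * 27, ""]
        for hyp, grp in self.rows.groupby("hypothesis", sort=False):
            out.append(hyp)
            for _, r in grp.iterrows():
                out.append(
                    f"  {r['test']:<55s} {r['kind']:>4s} stat={r['statistic']:10.3f} "
                    f"df={int(r['df']):3d}  p={r['p_value']:.4g}"
                )
            out.append("")
        return "\n".join(out)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def hypothesis_battery(
    data: ObservationTable,
    spec: DesignSpec | None = None,
    options: FitOptions | None = None,
) -> BatteryReport:
    """Fit the full correlated-random-effects model and test the study's
    four clinical null hypotheses.

    * equality of arms — joint Wald on the affected-side intercepts plus
      every term that distinguishes the arms, and the LRT of the full model
      against the model without the affected-side interaction covariates
      (16 df) and without all arm-specific modification terms (32 df);
    * pain — overall-effect Wald tests of SPADI pain on the unaffected arm
      and of its affected-side interaction;
    * clinical risk factors — overall-effect Wald test per clinical
      covariate;
    * effect modification — overall-effect Wald test per affected-side
      interaction term.
    """
    spec = spec or default_design_spec()
    options = options or FitOptions()
    if options.estimation != "ML":
        raise NestingError("the battery compares fixed effects and requires ML estimation")

    full = fit(data, spec, "model6", options)
    rows = []

    def add(hyp, test, res):
        if isinstance(res, WaldResult):
            rows.append(
                dict(hypothesis=hyp, test=test, kind="Wald", statistic=res.statistic, df=res.df, p_value=res.p_value)
            )
        else:
            rows.append(
                dict(hypothesis=hyp, test=test, kind="LRT", statistic=res.delta_deviance, df=res.df, p_value=res.p_value)
            )

    fits = {"full": full}

    # --- equality of arms -------------------------------------------------
    hyp = "equality of arms (affected vs unaffected)"
    if "affected" in spec.main_effects:
        add(hyp, "affected-side intercepts (all muscles)", collective_wald(full, "affected"))
    arm_terms = (
        ([f"{t}:affected" for t in spec.affected_interactions])
        + [f"{t}@affected" for t in spec.affected_only]
        + (["affected"] if "affected" in spec.main_effects else [])
    )
    labels = [f"{m}.{t}" for t in arm_terms for m in MUSCLES]
    if labels:
        add(
            hyp,
            "all arm-distinguishing terms jointly",
            wald_test(full, labels, description="arms jointly"),
        )
    if spec.affected_interactions:
        reduced_int = fit(data, drop_terms(spec, ["affected_interactions"]), "model6", options)
        fits["no_interactions"] = reduced_int
        add(hyp, "LRT: drop affected-side interaction covariates", lrt(reduced_int, full))
    if spec.affected_interactions or spec.affected_only:
        reduced_all = fit(
            data, drop_terms(spec, ["affected_interactions", "affected_only"]), "model6", options
        )
        fits["no_arm_terms"] = reduced_all
        add(hyp, "LRT: drop all arm-specific modification terms", lrt(reduced_all, full))

    # --- pain and dysfunction --------------------------------------------
    hyp = "pain and dysfunction (SPADI)"
    for term, desc in (
        ("spadi_pain", "SPADI pain, unaffected-arm effect"),
        ("spadi_pain:affected", "SPADI pain x affected side"),
        ("spadi_disability", "SPADI disability, unaffected-arm effect"),
    ):
        if term in spec.terms:
            add(hyp, desc, collective_wald(full, term))

    # --- clinical risk factors -------------------------------------------
    hyp = "clinical risk factors"
    for term in ("wle", "chemo", "duration", "age", "hand_left", "dominant"):
        if term in spec.main_effects:
            add(hyp, f"overall effect of {term}", collective_wald(full, term))
    for term in spec.affected_only:
        add(hyp, f"{term} (affected arm only)", collective_wald(full, f"{term}@affected"))

    # --- effect modification by affected side ----------------------------
    hyp = "effect modification by affected side"
    for term in spec.affected_interactions:
        add(hyp, f"{term} x affected", collective_wald(full, f"{term}:affected"))

    return BatteryReport(rows=pd.DataFrame(rows), fits=fits)
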