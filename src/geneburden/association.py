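"""Gene-burden association testing.

The principal analysis collapses each sample's genotypes over a gene's
qualifying variants into a single 0/1 carrier indicator and fits

    logit P(case) = b0 + b * carrier + sum_s g_s * I(study = s)

by maximum likelihood.  The odds ratio is ``exp(b)`` with a Wald 95%
confidence interval ``exp(b ± 1.96·SE)`` and a two-sided Wald p-value; the
study covariate absorbs between-stratum differences in baseline carrier
odds and case-control mix.  With a single stratum the fitted odds ratio
equals the 2×2 cross-product ratio exactly.

When one outcome group has zero carriers the likelihood diverges (complete
separation).  The fit is then run to an iteration cap and reported in the
conventional diverged form — OR coded 0 or +inf by the sign of the runaway
coefficient, CI (0, inf), and the (large) Wald p of the capped fit — with a
``separation_flag`` set.  No penalised correction is applied, matching the
convention of reporting divergent cells honestly rather than shrinking them.

Subtype analyses restrict the cases to one estrogen-receptor (ER) label and
compare them against all controls; cases with the other or unknown label are
dropped.  A case-only logistic regression of ER label on carrier status
(study-adjusted) provides the between-subtype heterogeneity p-value; a
per-study view uses Fisher's exact test on the crude 2×2 table.  A
single-variant screen tests individual variants seen in at least
``min_total`` carriers of whom at least ``min_case`` are cases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "AssociationResult",
    "HeterogeneityResult",
    "collapse_carriers",
    "fit_burden_logistic",
    "fisher_burden",
    "subtype_association",
    "heterogeneity_pdiff",
    "single_variant_screen",
    "run_association_suite",
]

Z_95 = 1.959964  # two-sided 95% normal quantile

#: |coefficient| beyond which a burden fit is treated as diverged.
_SEPARATION_BETA = 15.0


@dataclass
class AssociationResult:
    """One association-table row (one gene/variant × class × subgroup)."""

    gene_id: str
    variant_class: str
    subgroup: str
    n_carrier_cases: int
    n_carrier_controls: int
    n_cases: int
    n_controls: int
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str = "wald_logistic"
    separation_flag: bool = False
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class HeterogeneityResult:
    gene_id: str
    variant_class: str
    p_diff: float | None
    method: str
    n_carrier_er_neg: int = 0
    n_carrier_er_pos: int = 0


def collapse_carriers(
    genotypes: np.ndarray,
    variant_index: Mapping[str, int],
    variant_sets: Mapping[str, object],
    classes: Sequence[str] = ("lof", "missense", "combined"),
) -> pd.DataFrame:
    """Collapse genotypes into per-gene, per-class 0/1 carrier indicators.

    A sample is a carrier of a gene/class iff it holds at least one
    alternate allele of at least one qualifying variant of that class
    (missing genotypes, coded negative, do not make a carrier).  The
    combined class is the elementwise OR of LoF and missense.  Returns a
    DataFrame with one column per ``gene_id:class`` and one row per sample.
    """
    cols: dict[str, np.ndarray] = {}
    for gene_id, vs in variant_sets.items():
        for klass in classes:
            keys = getattr(vs, klass)
            idx = [variant_index[k] for k in keys if k in variant_index]
            missing = [k for k in keys if k not in variant_index]
            if missing:
                raise KeyError(
                    f"variants in set but absent from genotypes: {missing[:3]}"
                )
            if idx:
                carrier = (genotypes[:, idx] > 0).any(axis=1).astype(np.int8)
            else:
                carrier = np.zeros(genotypes.shape[0], dtype=np.int8)
            cols[f"{gene_id}:{klass}"] = carrier
    return pd.DataFrame(cols)


def _counts(carrier: np.ndarray, status: np.ndarray) -> tuple[int, int, int, int]:
    case = status == 1
    return (
        int(carrier[case].sum()),
        int(carrier[~case].sum()),
        int(case.sum()),
        int((~case).sum()),
    )


def fit_burden_logistic(
    carrier: np.ndarray,
    status: np.ndarray,
    study: np.ndarray | None = None,
    gene_id: str = "",
    variant_class: str = "",
    subgroup: str = "overall",
    maxiter: int = 25,
) -> AssociationResult:
    """Maximum-likelihood logistic burden fit with a study covariate.

    ``carrier`` is 0/1, ``status`` is 1 for cases and 0 for controls,
    ``study`` holds stratum labels (may be omitted or constant for a
    single-stratum fit).  Stratum indicators drop the lexicographically
    first label as reference.  Internally the data are aggregated to unique
    (status, carrier, stratum) cells with frequency weights, which leaves
    the likelihood, estimates and standard errors identical to the
    per-sample fit.

    Zero carriers among cases or controls produce a separation-flagged
    result with the OR coded 0 or +inf by the sign of the diverging
    coefficient and CI (0, inf); the Wald p of the iteration-capped fit is
    reported.  Degenerate inputs (no carriers anywhere, or all carriers, or
    a single outcome class) are flagged and given a null placeholder.
    """
    carrier = np.asarray(carrier).astype(int)
    status = np.asarray(status).astype(int)
    if study is None:
        study = np.zeros(len(carrier), dtype=object)
    study = np.asarray(study, dtype=object)
    ncc, ncn, n_cases, n_controls = _counts(carrier, status)

    def _result(or_, lo, hi, p, sep=False, degen=False):
        return AssociationResult(
            gene_id=gene_id, variant_class=variant_class, subgroup=subgroup,
            n_carrier_cases=ncc, n_carrier_controls=ncn,
            n_cases=n_cases, n_controls=n_controls,
            or_estimate=or_, ci_low=lo, ci_high=hi, p_value=p,
            method="wald_logistic", separation_flag=sep, degenerate=degen,
        )

    if n_cases == 0 or n_controls == 0:
        return _result(np.nan, np.nan, np.nan, np.nan, degen=True)
    if carrier.min() == carrier.max():  # no carriers at all, or everyone
        return _result(np.nan, np.nan, np.nan, np.nan, degen=True)

    cells = pd.DataFrame({"y": status, "carrier": carrier, "study": study})
    agg = cells.groupby(["y", "carrier", "study"], sort=True).size().reset_index(name="w")
    X = pd.get_dummies(agg[["carrier", "study"]], columns=["study"], drop_first=True, dtype=float)
    X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(
            agg["y"], X, family=sm.families.Binomial(), freq_weights=agg["w"]
        ).fit(maxiter=maxiter)
    beta = float(fit.params["carrier"])
    se = float(fit.bse["carrier"])
    p = float(fit.pvalues["carrier"])

    separated = ncc == 0 or ncn == 0 or abs(beta) > _SEPARATION_BETA
    if separated:
        or_code = np.inf if beta > 0 else 0.0
        return _result(or_code, 0.0, np.inf, p, sep=True)
    return _result(
        float(np.exp(beta)),
        float(np.exp(beta - Z_95 * se)),
        float(np.exp(beta + Z_95 * se)),
        p,
    )


def fisher_burden(
    n_carrier_cases: int,
    n_cases: int,
    n_carrier_controls: int,
    n_controls: int,
) -> tuple[float, float]:
    """Crude odds ratio and two-sided Fisher exact p of a carrier 2×2 table.

    The OR is the cross-product ratio, coded 0 or +inf on zero cells (NaN
    for 0/0); the p-value sums hypergeometric point probabilities no larger
    than the observed table's.
    """
    a, b = n_carrier_cases, n_cases - n_carrier_cases
    c, d = n_carrier_controls, n_controls - n_carrier_controls
    if min(a, b, c, d) < 0:
        raise ValueError("carrier counts exceed group sizes")
    if a * d == 0 and c * b == 0:
        or_ = np.nan
    elif c * b == 0:
        or_ = np.inf
    else:
        or_ = (a * d) / (c * b)
    _, p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return or_, float(p)


def subtype_association(
    carrier: np.ndarray,
    samples: pd.DataFrame,
    subtype: str,
    gene_id: str = "",
    variant_class: str = "",
    maxiter: int = 25,
) -> AssociationResult | None:
    """ER-subtype burden fit: cases with ER label ``subtype`` ('er_neg' or
    'er_pos') against all controls; other and unknown-ER cases are dropped.
    Returns ``None`` when no case carries the requested label."""
    label = {"er_neg": "neg", "er_pos": "pos"}[subtype]
    status = (samples["status"] == "case").to_numpy().astype(int)
    keep = (status == 0) | ((status == 1) & (samples["er_status"] == label).to_numpy())
    if not ((status == 1) & keep).any():
        return None
    return fit_burden_logistic(
        np.asarray(carrier)[keep], status[keep], samples["study"].to_numpy()[keep],
        gene_id=gene_id, variant_class=variant_class, subgroup=subtype,
        maxiter=maxiter,
    )


def heterogeneity_pdiff(
    carrier: np.ndarray,
    samples: pd.DataFrame,
    gene_id: str = "",
    variant_class: str = "",
    method: str = "logistic",
    maxiter: int = 25,
) -> HeterogeneityResult:
    """Between-subtype heterogeneity of the carrier effect.

    Case-only comparison of carrier frequency between ER-negative and
    ER-positive cases.  ``method='logistic'`` (default) regresses the ER
    label on carrier status with a study covariate and reports the Wald p of
    the carrier term; ``method='fisher'`` uses the exact test on the crude
    case-only 2×2 table.  Returns ``p_diff=None`` when no typed case
    carries a qualifying variant or a subtype has no cases.
    """
    is_case = (samples["status"] == "case").to_numpy()
    er = samples["er_status"].to_numpy()
    keep = is_case & np.isin(er, ("neg", "pos"))
    carrier = np.asarray(carrier).astype(int)[keep]
    er_neg = (er[keep] == "neg").astype(int)
    n_neg_car = int(carrier[er_neg == 1].sum())
    n_pos_car = int(carrier[er_neg == 0].sum())

    def _res(p, meth):
        return HeterogeneityResult(
            gene_id=gene_id, variant_class=variant_class, p_diff=p,
            method=meth, n_carrier_er_neg=n_neg_car, n_carrier_er_pos=n_pos_car,
        )

    if er_neg.min() == er_neg.max() or carrier.sum() == 0:
        return _res(None, method)
    if method == "fisher":
        _, p = fisher_burden(
            n_neg_car, int(er_neg.sum()), n_pos_car, int((1 - er_neg).sum())
        )
        return _res(p, "fisher")
    res = fit_burden_logistic(
        carrier, er_neg, samples["study"].to_numpy()[keep], maxiter=maxiter
    )
    if res.separation_flag or res.degenerate:
        # all carriers in one subtype: the Wald p of the diverged fit is
        # uninformative, so fall back to the exact case-only test
        _, p = fisher_burden(
            n_neg_car, int(er_neg.sum()), n_pos_car, int((1 - er_neg).sum())
        )
        return _res(p, "case_only_fisher_fallback")
    return _res(res.p_value, "case_only_logistic")


def single_variant_screen(
    variants: Sequence,
    genotypes: np.ndarray,
    samples: pd.DataFrame,
    min_total: int = 3,
    min_case: int = 2,
    maxiter: int = 25,
) -> pd.DataFrame:
    """Individual-variant association screen.

    Only variants observed in at least ``min_total`` carriers, of whom at
    least ``min_case`` are cases, are tested; each passes through the
    study-adjusted logistic fit on its own carrier vector.  Returns a
    DataFrame with one row per tested variant.
    """
    status = (samples["status"] == "case").to_numpy().astype(int)
    study = samples["study"].to_numpy()
    rows = []
    for j, v in enumerate(variants):
        carrier = (genotypes[:, j] > 0).astype(int)
        total = int(carrier.sum())
        in_cases = int(carrier[status == 1].sum())
        if total < min_total or in_cases < min_case:
            continue
        res = fit_burden_logistic(
            carrier, status, study, gene_id=v.gene_id,
            variant_class=v.consequence.value, subgroup="overall",
            maxiter=maxiter,
        )
        row = res.to_dict()
        row["variant_key"] = v.key
        rows.append(row)
    columns = [
        "variant_key", "gene_id", "variant_class", "subgroup",
        "n_carrier_cases", "n_carrier_controls", "n_cases", "n_controls",
        "or_estimate", "ci_low", "ci_high", "p_value", "method",
        "separation_flag", "degenerate",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class SuiteResults:
    """Bundle of association outputs: the gene × class × subgroup table,
    the single-variant screen, the heterogeneity table, and optional
    per-study Fisher tables."""

    gene_results: pd.DataFrame
    single_variant: pd.DataFrame
    heterogeneity: pd.DataFrame
    per_study: pd.DataFrame | None = None


def run_association_suite(
    samples: pd.DataFrame,
    variants: Sequence,
    genotypes: np.ndarray,
    variant_sets: Mapping[str, object],
    classes: Sequence[str] = ("lof", "missense", "combined"),
    subgroups: Sequence[str] = ("overall", "er_neg", "er_pos"),
    per_study: bool = False,
    heterogeneity_method: str = "logistic",
    single_variant_min_total: int = 3,
    single_variant_min_case: int = 2,
    maxiter: int = 25,
) -> SuiteResults:
    """Run the full association suite on a qualified dataset.

    Produces one row per gene per class per requested subgroup, plus the
    single-variant screen and the heterogeneity table; per-gene failures
    (degenerate cells, separation) are flagged in the rows, never raised.
    """
    variant_index = {v.key: j for j, v in enumerate(variants)}
    carriers = collapse_carriers(genotypes, variant_index, variant_sets, classes)
    status = (samples["status"] == "case").to_numpy().astype(int)
    study = samples["study"].to_numpy()

    gene_rows, het_rows, study_rows = [], [], []
    for gene_id in sorted(variant_sets):
        for klass in classes:
            carrier = carriers[f"{gene_id}:{klass}"].to_numpy()
            for sg in subgroups:
                if sg == "overall":
                    res = fit_burden_logistic(
                        carrier, status, study, gene_id=gene_id,
                        variant_class=klass, maxiter=maxiter,
                    )
                else:
                    res = subtype_association(
                        carrier, samples, sg, gene_id=gene_id,
                        variant_class=klass, maxiter=maxiter,
                    )
                if res is not None:
                    gene_rows.append(res.to_dict())
            het_rows.append(
                heterogeneity_pdiff(
                    carrier, samples, gene_id=gene_id, variant_class=klass,
                    method=heterogeneity_method, maxiter=maxiter,
                ).__dict__
            )
            if per_study:
                for lab in sorted(pd.unique(study)):
                    m = study == lab
                    ncc, ncn, ncase, nctrl = _counts(carrier[m], status[m])
                    or_, p = fisher_burden(ncc, ncase, ncn, nctrl)
                    study_rows.append(
                        AssociationResult(
                            gene_id=gene_id, variant_class=klass,
                            subgroup=f"per-study:{lab}",
                            n_carrier_cases=ncc, n_carrier_controls=ncn,
                            n_cases=ncase, n_controls=nctrl,
                            or_estimate=or_, ci_low=np.nan, ci_high=np.nan,
                            p_value=p, method="fisher",
                            separation_flag=(ncc == 0 or ncn == 0),
                        ).to_dict()
                    )

    sv = single_variant_screen(
        variants, genotypes, samples,
        min_total=single_variant_min_total, min_case=single_variant_min_case,
        maxiter=maxiter,
    )
    return SuiteResults(
        gene_results=pd.DataFrame(gene_rows),
        single_variant=sv,
        heterogeneity=pd.DataFrame(het_rows),
        per_study=pd.DataFrame(study_rows) if per_study else None,
    )
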