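"""Fixed-effect linear models for marker-trait association.

The model is the one-way fixed-effect ANOVA

    Y_ij = mu + G_i + e_ij

where Y_ij is a trait value, G_i the effect of genotype class (or breed) i
and e_ij iid Gaussian error. Fitting is ordinary least squares on the
cell-means parameterization, so with no covariate the least-squares (LS)
means are the arithmetic group means; with a covariate the LS means are
evaluated at the covariate's grand mean, and with breed as an additional
fixed effect they average the breed effects equally. Group differences are
summarized by the overall F test, pairwise t tests on LS-mean differences
using the pooled residual variance (unadjusted by default; Bonferroni and
Tukey-Kramer selectable) and a compact letter display in which groups
sharing a letter do not differ at the chosen alpha.

Variance homogeneity can be screened with the Brown-Forsythe variant of
Levene's test (one-way ANOVA on absolute deviations from group medians),
run through the same engine.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import GenotypeTable, TraitTable

__all__ = [
    "DesignError",
    "DesignSpec",
    "OnewayFitResult",
    "study_frame",
    "fit_oneway",
    "pairwise_ttests",
    "compact_letter_display",
    "levene_test",
    "association_scan",
    "breed_summary",
    "filter_outliers",
    "render_scan_markdown",
    "render_breed_summary_markdown",
]


class DesignError(ValueError):
    """The requested model cannot be fit (too few levels or residual df)."""


@dataclass
class DesignSpec:
    """One model specification: response trait, grouping factor, options.

    ``factor`` is a column of the study frame ("breed" or a locus id);
    ``covariate`` an optional numeric column entering as a common slope;
    ``extra_factor`` an optional second categorical fixed effect (e.g. breed
    in a genotype model). ``population`` restricts to one breed.
    """

    response: str
    factor: str
    covariate: str | None = None
    extra_factor: str | None = None
    population: str | None = None
    level_order: list | None = None
    alpha: float = 0.05
    adjust: str = "none"  # none | bonferroni | tukey


@dataclass
class OnewayFitResult:
    """A fitted one-way (optionally covariate/extra-factor) model."""

    levels: list
    ns: dict
    ls_means: dict
    se: dict
    residual_variance: float
    df_factor: int
    df_error: int
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame
    letters: dict
    alpha: float
    dropped_levels: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    _vcov_means: np.ndarray | None = None


def study_frame(genotypes: GenotypeTable, traits: TraitTable | None = None) -> pd.DataFrame:
    """Tidy per-sample frame: sample_id, breed, one genotype column per locus,
    one numeric column per trait. Missing calls/values become NaN."""
    rows = []
    trait_names = traits.trait_names() if traits is not None else []
    for s in genotypes.samples:
        row = {"sample_id": s.sample_id, "breed": s.breed}
        for locus in genotypes.loci:
            call = s.calls.get(locus.locus_id)
            row[locus.locus_id] = (
                np.nan if call is None or call.is_missing else call.to_string()
            )
        if traits is not None:
            tvals = traits.values.get(s.sample_id, {})
            for t in trait_names:
                v = tvals.get(t)
                row[t] = np.nan if v is None else float(v)
        rows.append(row)
    return pd.DataFrame(rows)


def _prepare(data: pd.DataFrame, spec: DesignSpec):
    df = data
    if spec.population is not None:
        df = df[df["breed"] == spec.population]
    if spec.response not in df.columns:
        raise DesignError(f"response trait {spec.response!r} not in data")
    if spec.factor not in df.columns:
        raise DesignError(f"factor {spec.factor!r} not in data")
    keep = df[spec.response].notna() & df[spec.factor].notna()
    if spec.covariate is not None:
        keep &= df[spec.covariate].notna()
    df = df[keep]
    if spec.level_order is not None:
        observed = [lv for lv in spec.level_order if (df[spec.factor] == lv).any()]
        dropped = [lv for lv in spec.level_order if lv not in observed]
    else:
        observed = list(pd.unique(df[spec.factor]))
        dropped = []
    df = df[df[spec.factor].isin(observed)]
    return df, observed, dropped


def fit_oneway(data: pd.DataFrame, spec: DesignSpec) -> OnewayFitResult:
    """OLS fit of trait ~ factor (+ covariate, + extra factor).

    Cell-means parameterization: one coefficient per factor level. The F
    statistic compares the factor's incremental sum of squares (factor added
    last) to the residual mean square. LS means are the level coefficients
    with the covariate held at its grand mean and any extra factor's effects
    averaged equally across its levels.
    """
    df, levels, dropped = _prepare(data, spec)
    if len(levels) < 2:
        raise DesignError(
            f"factor {spec.factor!r} has {len(levels)} observed level(s); need >= 2"
        )
    if dropped:
        _warnings.warn(f"dropping empty factor level(s) {dropped} of {spec.factor!r}")
    y = df[spec.response].to_numpy(dtype=float)
    n = len(y)
    k = len(levels)
    level_idx = {lv: i for i, lv in enumerate(levels)}
    X_factor = np.zeros((n, k))
    for row, lv in enumerate(df[spec.factor]):
        X_factor[row, level_idx[lv]] = 1.0

    # extra design columns and their weights in the LS-mean contrast
    Z_cols, z_weights = [], []
    if spec.extra_factor is not None:
        extra_levels = list(pd.unique(df[spec.extra_factor]))
        for lv in extra_levels[1:]:  # first level absorbed by cell means
            Z_cols.append((df[spec.extra_factor] == lv).to_numpy(dtype=float))
            z_weights.append(1.0 / len(extra_levels))
    if spec.covariate is not None:
        x = df[spec.covariate].to_numpy(dtype=float)
        Z_cols.append(x - x.mean())  # centered: LS means at covariate grand mean
        z_weights.append(0.0)

    X = np.column_stack([X_factor] + [c[:, None] for c in Z_cols]) if Z_cols else X_factor
    p_full = X.shape[1]
    df_error = n - p_full
    if df_error < 1:
        raise DesignError("zero residual degrees of freedom")

    XtX = X.T @ X
    XtX_inv = np.linalg.pinv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    sse_full = float(resid @ resid)
    sigma2 = sse_full / df_error

    # reduced model: everything except the factor (intercept + Z)
    ones = np.ones((n, 1))
    X_red = np.column_stack([ones] + [c[:, None] for c in Z_cols]) if Z_cols else ones
    beta_red, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    resid_red = y - X_red @ beta_red
    sse_red = float(resid_red @ resid_red)

    df_factor = k - 1
    ss_factor = max(sse_red - sse_full, 0.0)
    if sigma2 > 0:
        f_stat = (ss_factor / df_factor) / sigma2
    else:
        f_stat = 0.0 if ss_factor <= 1e-12 else np.inf
    p_value = float(stats.f.sf(f_stat, df_factor, df_error)) if np.isfinite(f_stat) else 0.0

    # LS-mean contrasts: e_i on the level block, fixed weights on Z
    C = np.zeros((k, p_full))
    for i in range(k):
        C[i, i] = 1.0
        for j, w in enumerate(z_weights):
            C[i, k + j] = w
    means_vec = C @ beta
    vcov_means = sigma2 * (C @ XtX_inv @ C.T)
    se_vec = np.sqrt(np.maximum(np.diag(vcov_means), 0.0))

    ns = {lv: int((df[spec.factor] == lv).sum()) for lv in levels}
    ls_means = {lv: float(means_vec[i]) for i, lv in enumerate(levels)}
    se = {lv: float(se_vec[i]) for i, lv in enumerate(levels)}

    result = OnewayFitResult(
        levels=levels,
        ns=ns,
        ls_means=ls_means,
        se=se,
        residual_variance=sigma2,
        df_factor=df_factor,
        df_error=df_error,
        f_stat=float(f_stat),
        p_value=p_value,
        pairwise=pd.DataFrame(),
        letters={},
        alpha=spec.alpha,
        dropped_levels=dropped,
        _vcov_means=vcov_means,
    )
    result.pairwise = pairwise_ttests(result, adjust=spec.adjust)
    letter_levels = [lv for lv in levels if ns[lv] >= 2]
    if len(letter_levels) < len(levels):
        skipped = [lv for lv in levels if ns[lv] < 2]
        result.warnings.append(
            f"level(s) {skipped} have n < 2 and are excluded from letter grouping"
        )
    result.letters = compact_letter_display(
        result.pairwise, result.ls_means, alpha=spec.alpha, levels=letter_levels
    )
    return result


def pairwise_ttests(fit: OnewayFitResult, adjust: str = "none") -> pd.DataFrame:
    """Two-sided pairwise tests on LS-mean differences.

    Uses the pooled residual variance and the fit's error df. ``adjust`` is
    "none" (Fisher-LSD style, the default letter-report convention),
    "bonferroni", or "tukey" (Tukey-Kramer via the studentized range).
    Returns a symmetric p-value matrix with unit diagonal.
    """
    if adjust not in ("none", "bonferroni", "tukey"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    levels = fit.levels
    k = len(levels)
    vcov = fit._vcov_means
    P = np.ones((k, k))
    m = k * (k - 1) / 2
    for i in range(k):
        for j in range(i + 1, k):
            diff = fit.ls_means[levels[i]] - fit.ls_means[levels[j]]
            var_diff = vcov[i, i] + vcov[j, j] - 2 * vcov[i, j]
            if var_diff <= 0:
                p = 1.0 if abs(diff) < 1e-12 else 0.0
            elif adjust == "tukey":
                q = abs(diff) / np.sqrt(var_diff / 2.0)
                p = float(stats.studentized_range.sf(q, k, fit.df_error))
            else:
                t = diff / np.sqrt(var_diff)
                p = 2.0 * float(stats.t.sf(abs(t), fit.df_error))
                if adjust == "bonferroni":
                    p = min(1.0, p * m)
            P[i, j] = P[j, i] = p
    return pd.DataFrame(P, index=levels, columns=levels)


def compact_letter_display(pairwise: pd.DataFrame, means: dict, alpha: float = 0.05, levels=None) -> dict:
    """Letter groups from a symmetric p-value matrix (insert-and-absorb).

    Starting from one group holding every level, each significant pair
    (taken in descending-mean sweep order) splits the groups containing
    both members; groups contained in another are absorbed. The result is a
    cover in which two levels share a letter iff their pairwise p >= alpha;
    letters are ordered by each group's best mean. Deterministic; ties in
    means break by level name.
    """
    if levels is None:
        levels = list(pairwise.index)
    if not levels:
        return {}
    order = sorted(levels, key=lambda lv: (-means[lv], str(lv)))
    rank = {lv: i for i, lv in enumerate(order)}

    groups: list[set] = [set(order)]
    sig_pairs = [
        (a, b)
        for i, a in enumerate(order)
        for b in order[i + 1:]
        if pairwise.loc[a, b] < alpha
    ]
    for a, b in sig_pairs:
        next_groups = []
        for g in groups:
            if a in g and b in g:
                next_groups.append(g - {a})
                next_groups.append(g - {b})
            else:
                next_groups.append(g)
        # absorb: drop any group contained in (or equal to) another
        groups = []
        for g in next_groups:
            if any(g < h for h in next_groups) or g in groups:
                continue
            groups.append(g)
    groups.sort(key=lambda g: min(rank[lv] for lv in g))
    letters = {lv: "" for lv in order}
    for letter_i, g in enumerate(groups):
        ch = chr(ord("a") + letter_i)
        for lv in order:
            if lv in g:
                letters[lv] += ch
    return letters


def levene_test(data: pd.DataFrame, spec: DesignSpec) -> tuple:
    """Brown-Forsythe homogeneity-of-variance test.

    One-way ANOVA (through :func:`fit_oneway`) on absolute deviations from
    the group medians. Returns ``(statistic, p_value)``.
    """
    df, levels, _ = _prepare(data, spec)
    if len(levels) < 2:
        raise DesignError("Levene's test needs >= 2 groups")
    df = df.copy()
    med = df.groupby(spec.factor)[spec.response].transform("median")
    df["_absdev"] = (df[spec.response] - med).abs()
    sub = DesignSpec(response="_absdev", factor=spec.factor, level_order=levels, alpha=spec.alpha)
    fit = fit_oneway(df, sub)
    return fit.f_stat, fit.p_value


def filter_outliers(data: pd.DataFrame, traits, z: float = 3.5, by: str = "breed"):
    """Optional within-group outlier screen: blank trait values with |z| > z.

    Returns ``(filtered copy, log)`` where the log lists every removal as
    ``(sample_id, trait, value, zscore)``. Off by default in every pipeline
    entry point; group means/SDs are computed per ``by`` level.
    """
    df = data.copy()
    removed = []
    for trait in traits:
        if trait not in df.columns:
            continue
        grp = df.groupby(by)[trait]
        mu = grp.transform("mean")
        sd = grp.transform("std")
        with np.errstate(invalid="ignore", divide="ignore"):
            zs = (df[trait] - mu) / sd
        mask = zs.abs() > z
        for _, row in df[mask].iterrows():
            removed.append((row["sample_id"], trait, float(row[trait]), float(zs[row.name])))
        df.loc[mask, trait] = np.nan
    return df, removed


GENOTYPE_LEVEL_ORDER = ("refref", "refalt", "altalt")


def _genotype_levels(locus):
    hom_ref = locus.ref_allele * 2
    het = "".join(sorted(locus.ref_allele + locus.alt_allele))
    hom_alt = locus.alt_allele * 2
    return [hom_ref, het, hom_alt]


def association_scan(
    genotypes: GenotypeTable,
    traits: TraitTable,
    loci=None,
    trait_names=None,
    model: str = "pooled",
    covariate: str | None = None,
    alpha: float = 0.05,
    adjust: str = "none",
    outlier_filter: bool = False,
) -> pd.DataFrame:
    """Per-locus, per-trait association scan (the marker-trait report).

    For every locus x trait cell, fits trait ~ genotype and reports LS means
    per genotype class, the overall F-test p-value and letter groups.
    ``model`` is "pooled" (genotype only, breeds pooled — the default),
    "breed-factor" (breed as an additional fixed effect) or "age-covariate"
    (requires ``covariate``). Loci with < 2 observed genotype classes are
    reported as non-testable.
    """
    if model not in ("pooled", "breed-factor", "age-covariate"):
        raise ValueError(f"unknown model mode {model!r}")
    if model == "age-covariate" and covariate is None:
        raise ValueError("age-covariate model needs covariate=")
    data = study_frame(genotypes, traits)
    if trait_names is None:
        trait_names = traits.trait_names()
    missing = [t for t in trait_names if t not in data.columns]
    if missing:
        raise DesignError(f"trait(s) {missing} not present in trait table")
    if loci is None:
        loci = genotypes.loci
    if outlier_filter:
        data, _ = filter_outliers(data, trait_names)
    rows = []
    for locus in loci:
        level_order = _genotype_levels(locus)
        for trait in trait_names:
            base = {"locus": locus.locus_id, "site": locus.display_name, "trait": trait}
            spec = DesignSpec(
                response=trait,
                factor=locus.locus_id,
                level_order=level_order,
                extra_factor="breed" if model == "breed-factor" else None,
                covariate=covariate if model == "age-covariate" else None,
                alpha=alpha,
                adjust=adjust,
            )
            try:
                with _warnings.catch_warnings():
                    _warnings.simplefilter("ignore")
                    fit = fit_oneway(data, spec)
            except DesignError as exc:
                rows.append({**base, "testable": False, "note": str(exc)})
                continue
            row = {**base, "testable": True, "note": "; ".join(fit.warnings),
                   "f_stat": fit.f_stat, "p_value": fit.p_value,
                   "df_factor": fit.df_factor, "df_error": fit.df_error}
            for g_label, g in zip(GENOTYPE_LEVEL_ORDER, level_order):
                row[f"n_{g_label}"] = fit.ns.get(g, 0)
                row[f"lsmean_{g_label}"] = fit.ls_means.get(g, np.nan)
                row[f"se_{g_label}"] = fit.se.get(g, np.nan)
                row[f"letters_{g_label}"] = fit.letters.get(g, "")
            if fit.dropped_levels:
                row["note"] = (row["note"] + "; " if row["note"] else "") + (
                    f"dropped genotype class(es) {fit.dropped_levels}"
                )
            rows.append(row)
    return pd.DataFrame(rows)


def breed_summary(
    genotypes: GenotypeTable,
    traits: TraitTable,
    trait_names=None,
    alpha: float = 0.05,
    adjust: str = "none",
) -> pd.DataFrame:
    """Per-trait, per-breed mean +/- sample SD with F test and letters.

    SD uses the n-1 denominator and is missing for breeds with n = 1; such
    breeds keep their mean but are excluded from the letter groups. Requires
    at least two breeds.
    """
    data = study_frame(genotypes, traits)
    if data["breed"].nunique() < 2:
        raise DesignError("breed summary needs >= 2 breeds")
    if trait_names is None:
        trait_names = traits.trait_names()
    breeds = genotypes.breeds
    rows = []
    for trait in trait_names:
        spec = DesignSpec(response=trait, factor="breed", level_order=breeds,
                          alpha=alpha, adjust=adjust)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = fit_oneway(data, spec)
        for breed in breeds:
            vals = data.loc[data["breed"] == breed, trait].dropna()
            n = len(vals)
            rows.append({
                "trait": trait,
                "breed": breed,
                "n": n,
                "mean": float(vals.mean()) if n else np.nan,
                "sd": float(vals.std(ddof=1)) if n >= 2 else np.nan,
                "letters": fit.letters.get(breed, ""),
                "p_value": fit.p_value,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report rendering


def render_scan_markdown(scan: pd.DataFrame) -> str:
    """Markdown table shaped like the conventional marker-trait report:
    one block per locus with one row per genotype class and one p-value row,
    traits as columns, superscript letters on the LS means."""
    traits = list(dict.fromkeys(scan["trait"]))
    lines = ["| SNP | Genotype | " + " | ".join(traits) + " |",
             "|---|---|" + "---|" * len(traits)]
    for locus in dict.fromkeys(scan["locus"]):
        block = scan[scan["locus"] == locus].set_index("trait")
        site = block["site"].iloc[0]
        for g_label, g_name in zip(GENOTYPE_LEVEL_ORDER, ("ref-hom", "het", "alt-hom")):
            cells = []
            for t in traits:
                r = block.loc[t]
                if not r.get("testable", True) or pd.isna(r.get(f"lsmean_{g_label}", np.nan)):
                    cells.append("-")
                else:
                    letters = r[f"letters_{g_label}"]
                    sup = f" ^{letters}^" if letters else ""
                    cells.append(f"{r[f'lsmean_{g_label}']:.2f}{sup}")
            lines.append(f"| {locus}: {site} | {g_name} | " + " | ".join(cells) + " |")
        pcells = []
        for t in traits:
            r = block.loc[t]
            pcells.append(f"{r['p_value']:.2f}" if r.get("testable", False) else "NT")
        lines.append(f"| {locus} | p-value | " + " | ".join(pcells) + " |")
    return "\n".join(lines)


def render_breed_summary_markdown(summary: pd.DataFrame) -> str:
    """Markdown table of per-breed trait means +/- SD with letters."""
    breeds = list(dict.fromkeys(summary["breed"]))
    lines = ["| Trait | " + " | ".join(breeds) + " | p-value |",
             "|---|" + "---|" * (len(breeds) + 1)]
    for trait in dict.fromkeys(summary["trait"]):
        block = summary[summary["trait"] == trait].set_index("breed")
        cells = []
        for b in breeds:
            r = block.loc[b]
            sd = "NA" if pd.isna(r["sd"]) else f"{r['sd']:.2f}"
            sup = f" ^{r['letters']}^" if r["letters"] else ""
            cells.append(f"{r['mean']:.2f} ± {sd}{sup}")
        p = block["p_value"].iloc[0]
        lines.append(f"| {trait} | " + " | ".join(cells) + f" | {p:.3g} |")
    return "\n".join(lines)
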