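"""Expression-matrix normalization/clustering, qPCR relative expression,
one-way ANOVA with Duncan's multiple range test, and Pearson correlation.

Expression matrices are genes x tissues TPM tables.  The heatmap-style
normalization is lg = log10(TPM + 1) followed by a per-gene Z score
(population standard deviation); hierarchical clustering (average linkage)
on the Z layer splits the family into expression clusters reported in
order of descending mean lg expression, so cluster 1 is the high-expression
cluster.

qPCR relative expression uses the 2^(-ddCt) method: dCt = Ct(target) -
Ct(reference) per replicate, ddCt relative to the mean control dCt of the
same gene x cultivar, fold = 2^(-ddCt).  Treatment effects are assessed by
one-way ANOVA followed by Duncan's multiple range test, whose least
significant range for a span of p ordered means uses the studentized-range
quantile at the protection level alpha_p = 1 - (1 - alpha)^(p-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .io_formats import ValidationError

TREATMENTS = ("control", "Cu", "Zn", "Cd")


@dataclass
class ExpressionMatrix:
    """TPM matrix with derived lg and Z layers."""

    tpm: pd.DataFrame                 # genes x tissues
    lg: pd.DataFrame | None = None
    z: pd.DataFrame | None = None
    constant_genes: tuple[str, ...] = ()


def normalize_expression(tpm: pd.DataFrame) -> ExpressionMatrix:
    """lg = log10(TPM + 1); Z = per-gene standardization of the lg layer.

    Constant lg rows get an all-zero Z row and are flagged.
    """
    if (tpm.values < 0).any():
        raise ValidationError("negative TPM values")
    lg = np.log10(tpm + 1.0)
    mean = lg.mean(axis=1)
    sd = lg.std(axis=1, ddof=0)
    constant = sd[sd == 0].index
    sd_safe = sd.replace(0, 1.0)
    z = lg.sub(mean, axis=0).div(sd_safe, axis=0)
    z.loc[constant] = 0.0
    return ExpressionMatrix(tpm=tpm, lg=lg, z=z,
                            constant_genes=tuple(constant))


def cluster_genes(matrix: ExpressionMatrix, k: int = 2,
                  metric: str = "euclidean") -> dict[str, int]:
    """Agglomerative (average-linkage) clustering of genes on the Z layer.

    Returns gene -> cluster index (1-based); clusters are numbered by
    descending mean lg expression, so cluster 1 collects the
    high-expression genes.  ``metric`` is 'euclidean' or 'correlation'.
    """
    if matrix.z is None:
        matrix = normalize_expression(matrix.tpm)
    genes = list(matrix.z.index)
    if k > len(genes):
        raise ValidationError(f"k={k} exceeds gene count {len(genes)}")
    if k == len(genes):
        raw = np.arange(1, len(genes) + 1)
    else:
        Z = linkage(matrix.z.values, method="average", metric=metric)
        raw = fcluster(Z, t=k, criterion="maxclust")
    mean_lg = matrix.lg.mean(axis=1)
    order = sorted(set(raw),
                   key=lambda c: -mean_lg[[g for g, r in zip(genes, raw) if r == c]].mean())
    remap = {c: i + 1 for i, c in enumerate(order)}
    return {g: remap[c] for g, c in zip(genes, raw)}


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

QPCR_COLUMNS = ("gene", "cultivar", "treatment", "replicate",
                "ct_target", "ct_reference")


def validate_qpcr(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(QPCR_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"qPCR table missing columns: {sorted(missing)}")
    if not np.isfinite(table["ct_target"]).all() or not np.isfinite(table["ct_reference"]).all():
        raise ValidationError("non-finite Ct values")
    return table


def ddct(table: pd.DataFrame, control_label: str = "control") -> pd.DataFrame:
    """Relative expression 2^(-ddCt) per replicate, with per-cell summaries.

    Returns a DataFrame with one row per (gene, cultivar, treatment,
    replicate): columns dct, ddct, fold; plus mean/SE via groupby in
    :func:`ddct_summary`.  The calibrator is the mean control dCt of the
    same gene x cultivar.
    """
    table = validate_qpcr(table).copy()
    table["dct"] = table["ct_target"] - table["ct_reference"]
    out = []
    for (gene, cultivar), sub in table.groupby(["gene", "cultivar"], sort=True):
        ctrl = sub[sub["treatment"] == control_label]
        if ctrl.empty:
            raise ValidationError(
                f"no {control_label!r} group for gene {gene!r} cultivar {cultivar!r}")
        baseline = ctrl["dct"].mean()
        sub = sub.copy()
        sub["ddct"] = sub["dct"] - baseline
        sub["fold"] = 2.0 ** (-sub["ddct"])
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def ddct_summary(folds: pd.DataFrame) -> pd.DataFrame:
    """Mean fold and standard error over replicates per gene/cultivar/treatment."""
    g = folds.groupby(["gene", "cultivar", "treatment"], sort=True)["fold"]
    return pd.DataFrame({
        "mean_fold": g.mean(),
        "se": g.std(ddof=1) / np.sqrt(g.count()),
        "n": g.count(),
    }).reset_index()


# ---------------------------------------------------------------------------
# ANOVA + Duncan's multiple range test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuncanResult:
    f_statistic: float | None
    p_value: float | None
    means: dict[str, float]
    letters: dict[str, str]


def duncan_critical_range(alpha: float, span: int, df_error: int,
                          ms_error: float, n_harmonic: float) -> float:
    """Least significant range for a span of ``span`` ordered means.

    Uses the studentized-range quantile at Duncan's protection level
    alpha_p = 1 - (1 - alpha)^(span - 1).
    """
    alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
    q = stats.studentized_range.ppf(1.0 - alpha_p, span, df_error)
    return float(q) * math.sqrt(ms_error / n_harmonic)


def _letters_from_nonsig(group_order: list[str],
                         nonsig: set[frozenset[str]]) -> dict[str, str]:
    """Compact letter display from maximal contiguous non-significant runs.

    Because a range test declares two means different only when their span
    range exceeds the critical value, non-significant sets are contiguous
    runs in the mean-sorted order; each maximal run gets one letter.
    """
    n = len(group_order)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and all(
                frozenset((group_order[a], group_order[b])) in nonsig
                for a in range(i, j + 2) for b in range(a + 1, j + 2)):
            j += 1
        runs.append((i, j))
        i += 1
    # keep maximal runs only
    maximal = [r for r in runs
               if not any(o[0] <= r[0] and r[1] <= o[1] and o != r for o in runs)]
    letters = {g: "" for g in group_order}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, (s, e) in enumerate(sorted(maximal)):
        for g in group_order[s:e + 1]:
            letters[g] += alphabet[idx % len(alphabet)]
    return letters


def anova_duncan(groups: dict[str, list[float]],
                 alpha: float = 0.05) -> DuncanResult:
    """One-way ANOVA F/p and Duncan's MRT compact letter display.

    ``groups`` maps group label -> replicate values (>= 2 groups, >= 2
    replicates each).  With zero within-group variance everywhere, letters
    are assigned by exact mean equality and F is flagged undefined (None).
    """
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(f"group {label!r} has fewer than 2 replicates")
    labels = sorted(groups)
    arrays = [np.asarray(groups[l], dtype=float) for l in labels]
    means = {l: float(a.mean()) for l, a in zip(labels, arrays)}
    n_total = sum(len(a) for a in arrays)
    df_error = n_total - len(labels)
    ss_error = sum(((a - a.mean()) ** 2).sum() for a in arrays)

    if ss_error == 0:
        order = sorted(labels, key=lambda l: (-means[l], l))
        nonsig = {frozenset((a, b)) for a in labels for b in labels
                  if a != b and means[a] == means[b]}
        return DuncanResult(None, None, means,
                            _letters_from_nonsig(order, nonsig))

    f_stat, p_val = stats.f_oneway(*arrays)
    ms_error = ss_error / df_error
    n_harmonic = len(labels) / sum(1.0 / len(a) for a in arrays)

    order = sorted(labels, key=lambda l: (-means[l], l))
    nonsig: set[frozenset[str]] = set()
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            span = j - i + 1
            lsr = duncan_critical_range(alpha, span, df_error, ms_error, n_harmonic)
            if abs(means[order[i]] - means[order[j]]) < lsr:
                nonsig.add(frozenset((order[i], order[j])))
    return DuncanResult(float(f_stat), float(p_val), means,
                        _letters_from_nonsig(order, nonsig))


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson r at sample size n via the t distribution."""
    if n < 3:
        raise ValidationError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def significance_mark(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlate(expression: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Gene x trait Pearson correlations with significance marks.

    ``expression`` is samples x genes, ``traits`` samples x traits, indexed
    identically.  Constant columns yield NaN r flagged with mark 'nd'.
    """
    if not expression.index.equals(traits.index):
        raise ValidationError("expression and trait tables have different samples")
    n = len(expression.index)
    rows = []
    for gene in expression.columns:
        x = expression[gene].to_numpy(dtype=float)
        for trait in traits.columns:
            y = traits[trait].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append((gene, trait, math.nan, n, math.nan, "nd"))
                continue
            r, p = stats.pearsonr(x, y)
            rows.append((gene, trait, float(r), n, float(p), significance_mark(p)))
    return pd.DataFrame(rows, columns=["gene", "trait", "r", "n", "p", "mark"])
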