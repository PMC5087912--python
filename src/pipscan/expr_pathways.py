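"""Expression integration, group statistics and the pathway screens.

Binding calls are joined to a per-gene differential-expression table
(gene, log2FC, p; negative log2FC = down-regulated under treatment).
Group comparisons use Welch's unequal-variance t-test throughout; the
three-criteria pathway screen flags a pathway as a candidate off-target
only when (1) pathway-vs-other-genes, (2) bound-in-pathway-vs-non-bound,
and (3) bound-in-pathway-vs-other-bound expression differences are all
significant, with pathways carrying fewer than two bound genes excluded
before testing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# basic statistics
# ---------------------------------------------------------------------------

def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df, two-sided p)."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def variance_f_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided F test of the variance ratio var(A)/var(B)."""
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero variance in a group")
    f = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.sf(f, dfa, dfb), stats.f.cdf(f, dfa, dfb))
    return float(min(p, 1.0))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of >= 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


def bootstrap_group_p(
    group_a: Sequence[float],
    group_b: Sequence[float],
    trials: int = 1000,
    n: int = 100,
    seed: int = 0,
) -> float:
    """Median Welch p over bootstrap trials of size n per group.

    Each trial resamples n values with replacement from each group and
    computes a Welch t-test; the trials are summarized by their median p.
    """
    a, b = np.asarray(group_a, float), np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    rng = np.random.default_rng(seed)
    ra = a[rng.integers(0, len(a), size=(trials, n))]
    rb = b[rng.integers(0, len(b), size=(trials, n))]
    ma, mb = ra.mean(axis=1), rb.mean(axis=1)
    va, vb = ra.var(axis=1, ddof=1), rb.var(axis=1, ddof=1)
    se2 = va / n + vb / n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2**2 / ((va / n) ** 2 / (n - 1) + (vb / n) ** 2 / (n - 1))
    p = np.where(se2 == 0, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    return float(np.median(p))


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene, log2fc, p. Genes with multiple probes are
    collapsed to the probe with the smallest p."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    required = {"gene", "log2fc", "p"}
    if not required <= set(df.columns):
        raise ValueError(f"expression table must have columns {sorted(required)}")
    df = df.sort_values("p", kind="stable").drop_duplicates("gene", keep="first")
    return df.reset_index(drop=True)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT-style pathway sets: id <tab> description <tab> gene..."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 3:
                continue
            pathways[cols[0]] = {g for g in cols[2:] if g}
    return pathways


@dataclass(frozen=True)
class GroupComparison:
    """Bound vs comparison-group expression summary (means of -log2FC)."""

    mean_bound: float
    sem_bound: float
    n_bound: int
    mean_other: float
    sem_other: float
    n_other: int
    t: float
    p: float
    n_missing_expression: int


def binding_expression_summary(
    expression: pd.DataFrame,
    bound_genes: Iterable[str],
    universe: Iterable[str] | None = None,
) -> GroupComparison:
    """Compare mean -log2FC of bound genes against the rest.

    ``universe`` restricts the comparison group (e.g. motif-matched but
    unbound genes); by default it is every expressed gene. Bound genes
    without expression records are excluded and counted.
    """
    bound = set(bound_genes)
    expressed = set(expression["gene"])
    missing = len(bound - expressed)
    pool = expression if universe is None else expression[
        expression["gene"].isin(set(universe) | bound)
    ]
    is_bound = pool["gene"].isin(bound)
    va = (-pool.loc[is_bound, "log2fc"]).to_numpy()
    vb = (-pool.loc[~is_bound, "log2fc"]).to_numpy()
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("each expression group needs >= 2 genes")
    t, _, p = welch_t(va, vb)
    return GroupComparison(
        mean_bound=float(va.mean()),
        sem_bound=float(va.std(ddof=1) / np.sqrt(len(va))),
        n_bound=len(va),
        mean_other=float(vb.mean()),
        sem_other=float(vb.std(ddof=1) / np.sqrt(len(vb))),
        n_other=len(vb),
        t=t,
        p=p,
        n_missing_expression=missing,
    )


# ---------------------------------------------------------------------------
# pathway screens
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathwayTestResult:
    pathway: str
    n_genes: int
    n_bound: int
    p1: float | None  # pathway vs other genes
    p2: float | None  # bound-in-pathway vs non-bound genes
    p3: float | None  # bound-in-pathway vs other bound genes
    excluded: bool
    reason: str
    candidate: bool


def pathway_three_criteria(
    pathways: Mapping[str, set[str]],
    expression: pd.DataFrame,
    bound_genes: Iterable[str],
    alpha: float = 0.05,
) -> list[PathwayTestResult]:
    """The three-criteria candidate off-target screen over pathway sets.

    All three comparisons are Welch t-tests on log2FC. A pathway with
    fewer than two bound genes (or without expressed genes) is excluded
    before testing; excluded + tested = total supplied.
    """
    bound = set(bound_genes)
    expr = expression.set_index("gene")["log2fc"]
    all_genes = set(expr.index)
    bound_expressed = bound & all_genes
    results: list[PathwayTestResult] = []
    for pid, genes in pathways.items():
        in_path = genes & all_genes
        bound_in = in_path & bound_expressed
        if len(in_path) == 0:
            results.append(PathwayTestResult(
                pid, len(genes), 0, None, None, None, True,
                "no expression-covered genes", False))
            continue
        if len(bound_in) < 2:
            results.append(PathwayTestResult(
                pid, len(genes), len(bound_in), None, None, None, True,
                "fewer than 2 bound genes", False))
            continue
        other_genes = all_genes - in_path
        non_bound = all_genes - bound_expressed
        other_bound = bound_expressed - bound_in
        try:
            _, _, p1 = welch_t(expr[list(in_path)], expr[list(other_genes)])
            _, _, p2 = welch_t(expr[list(bound_in)], expr[list(non_bound)])
            _, _, p3 = welch_t(expr[list(bound_in)], expr[list(other_bound)])
        except ValueError as exc:
            results.append(PathwayTestResult(
                pid, len(genes), len(bound_in), None, None, None, True,
                f"untestable: {exc}", False))
            continue
        candidate = p1 < alpha and p2 < alpha and p3 < alpha
        results.append(PathwayTestResult(
            pid, len(genes), len(bound_in), p1, p2, p3, False, "", candidate))
    return results


def overrep_fold(found: float, expected: float) -> float:
    """Found/expected enrichment fold (reported to 2 decimals in tables)."""
    if expected <= 0:
        raise ValueError("expected count must be > 0")
    return found / expected


def overrep_test(
    category_hits: Mapping[str, int],
    category_genome: Mapping[str, int],
    list_size: int,
    genome_size: int,
    alpha: float = 0.05,
    method: str = "binomial",
) -> pd.DataFrame:
    """One-sided overrepresentation test per category, Bonferroni-corrected.

    The default binomial model tests the observed hit count in the gene
    list against the genome-wide category frequency; a hypergeometric
    model is available as an option. Categories absent from the genome
    annotation are skipped with a warning.
    """
    if method not in ("binomial", "hypergeometric"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for cat, hits in category_hits.items():
        genome_count = category_genome.get(cat, 0)
        if genome_count <= 0:
            log.warning("category %s absent from genome annotation, skipped", cat)
            continue
        freq = genome_count / genome_size
        expected = freq * list_size
        if method == "binomial":
            p = stats.binomtest(hits, list_size, freq, alternative="greater").pvalue
        else:
            p = stats.hypergeom.sf(hits - 1, genome_size, genome_count, list_size)
        rows.append({
            "category": cat,
            "found": hits,
            "expected": expected,
            "fold": overrep_fold(hits, expected) if expected > 0 else np.nan,
            "p_raw": float(p),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bonferroni"] = np.minimum(df["p_raw"] * len(df), 1.0)
        df["significant"] = df["p_bonferroni"] < alpha
    return df
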