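"""Mutation-burden tabulation and group-level cohort statistics.

Covers per-subject / per-gene mutation counts and every named test of the
analysis: Mann-Whitney for two groups (exact for small untied samples,
tie- and continuity-corrected normal approximation otherwise),
Kruskal-Wallis with Dunn's post hoc (rank-based z statistics with tie
correction, Bonferroni family-wise adjustment) for three, chi-squared for
base-prevalence contingency tables, Fisher's exact test with a Monte-Carlo
simulated p-value for haplogroup distributions, Pearson/Spearman
correlation behind a Lilliefors-corrected Kolmogorov-Smirnov normality
gate, and relative mtDNA copy number from qPCR Ct triplicates via
``2^(Ct_nDNA - Ct_mtDNA)``.

A position overlapping two annotated features (e.g. ATP8/ATP6) increments
the count of each feature, so gene columns may sum to more than the
subject's total, which counts each position once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .arraydata import SubjectMeta
from .calling import CallSet
from .reference import ReferenceGenome, gene_at

# ---------------------------------------------------------------------------
# study design bookkeeping

#: Printed subgroup sizes of the two cohorts: whole-blood cohort 1 split by
#: carrier status of a known ALS gene; cohort 2 (fresh PLT + WBC) split by
#: inheritance pattern and carrier status.  15 patients appear in both
#: cohorts (blood drawn at different time points), so unique patients are
#: counted once.
STUDY_DESIGN: dict = {
    "cohort1": {"known_als_gene": 27, "no_known_gene": 21},
    "cohort2": {
        "maternal_known_gene": 2,
        "maternal_no_known_gene": 4,
        "non_maternal_known_gene": 6,
        "non_maternal_no_known_gene": 10,
    },
    "overlap": 15,
}


def cohort_sizes(design: Mapping = STUDY_DESIGN) -> dict[str, int]:
    """Unique-subject arithmetic over the printed subgroup counts."""
    c1 = sum(design["cohort1"].values())
    c2 = sum(design["cohort2"].values())
    return {
        "cohort1": c1,
        "cohort2": c2,
        "total_unique": c1 + c2 - design["overlap"],
    }


# ---------------------------------------------------------------------------
# named tests

@dataclass
class TestReport:
    test: str
    statistic: float
    p: float
    n: tuple[int, ...]
    pairwise: pd.DataFrame | None = None
    note: str = ""


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestReport:
    """Two-sided Mann-Whitney U; exact when both n <= 8 and untied."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return TestReport("mannwhitney", float(len(x) * len(y) / 2), 1.0,
                          (len(x), len(y)), note="all values identical")
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestReport("mannwhitney", float(res.statistic), float(res.pvalue),
                      (len(x), len(y)), note=method)


def _dunn(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post hoc: tie-corrected rank z tests, Bonferroni adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    start = 0
    for g in names:
        k = groups[g].size
        mean_rank[g] = ranks[start:start + k].mean()
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12 - tie_term
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        se = math.sqrt(var_base * (1 / groups[a].size + 1 / groups[b].size))
        z = 0.0 if se == 0 else (mean_rank[a] - mean_rank[b]) / se
        p_raw = 2 * stats.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": z,
                     "p_unadjusted": p_raw, "p_adjusted": min(1.0, p_raw * m)})
    return pd.DataFrame(rows)


def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> TestReport:
    """Kruskal-Wallis H with Dunn's pairwise post hoc (Bonferroni)."""
    arrs = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    ns = tuple(a.size for a in arrs.values())
    pooled = np.concatenate(list(arrs.values()))
    if np.ptp(pooled) == 0:
        pw = _dunn(arrs)
        return TestReport("kruskal", 0.0, 1.0, ns, pairwise=pw,
                          note="all values identical")
    res = stats.kruskal(*arrs.values())
    return TestReport("kruskal", float(res.statistic), float(res.pvalue),
                      ns, pairwise=_dunn(arrs))


# ---------------------------------------------------------------------------
# burden tables

def burden_table(
    callsets: Sequence[CallSet],
    genome: ReferenceGenome,
    mutation_class: str,
) -> pd.DataFrame:
    """Subjects x genes table of mutation counts of one class.

    The ``total`` column counts each mutated position once; gene columns
    attribute overlap positions to every overlapping feature.
    """
    if mutation_class not in ("homoplasmic", "heteroplasmic"):
        raise ValueError(f"unknown mutation class {mutation_class!r}")
    gene_names = genome.gene_names()
    rows = []
    for cs in callsets:
        counts = dict.fromkeys(gene_names, 0)
        variants = cs.variants(mutation_class)
        for v in variants:
            for g in gene_at(genome, v.position):
                counts[g] += 1
        counts["total"] = len(variants)
        rows.append(pd.Series(counts, name=cs.subject_id))
    return pd.DataFrame(rows, columns=gene_names + ["total"]).fillna(0).astype(int)


def compare_burden_groups(
    table: pd.DataFrame,
    grouping: Mapping[str, str] | pd.Series,
) -> dict[str, TestReport]:
    """Group comparison per gene column: Mann-Whitney for two groups,
    Kruskal-Wallis + Dunn for three or more."""
    grouping = pd.Series(grouping)
    grouping = grouping.loc[grouping.index.intersection(table.index)]
    levels = sorted(grouping.unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    for g in levels:
        if (grouping == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
    out = {}
    for col in table.columns:
        by_group = {g: table.loc[grouping.index[grouping == g], col].to_numpy()
                    for g in levels}
        if len(levels) == 2:
            out[col] = mann_whitney(*by_group.values())
        else:
            out[col] = kruskal_dunn(by_group)
    return out


def onset_contrast(
    table: pd.DataFrame,
    meta: Sequence[SubjectMeta],
    gene: str,
) -> TestReport:
    """Bulbar vs spinal onset contrast on one gene's counts (Mann-Whitney).

    Subjects with unknown onset are excluded from n.
    """
    onset = {m.subject_id: m.onset_site for m in meta}
    groups: dict[str, list[float]] = {"bulbar": [], "spinal": []}
    for sid in table.index:
        site = onset.get(sid, "unknown")
        if site in groups:
            groups[site].append(float(table.loc[sid, gene]))
    if min(len(v) for v in groups.values()) < 3:
        raise ValueError(
            "onset contrast needs at least 3 subjects per onset class "
            f"(got bulbar={len(groups['bulbar'])}, spinal={len(groups['spinal'])})"
        )
    return mann_whitney(groups["bulbar"], groups["spinal"])


# ---------------------------------------------------------------------------
# base prevalence

@dataclass
class BasePrevalence:
    counts: pd.DataFrame       # bases x groups: mutated-position counts
    percentages: pd.DataFrame  # 100 * count / reference count of that base
    chi2: float | None
    p: float | None
    skipped: bool = False
    warning: str = ""


def base_prevalence(
    callsets_by_group: Mapping[str, Sequence[CallSet]],
    genome: ReferenceGenome,
    classes: tuple[str, ...] = ("homoplasmic", "heteroplasmic"),
) -> BasePrevalence:
    """Per-base mutation percentages per group plus the chi-squared test.

    Mutations are tallied by the *reference* base at the mutated position
    and normalised by how often that base occurs in the reference, since
    the four bases are unequally represented in the mtDNA sequence.
    """
    bases = ["A", "C", "G", "T"]
    comp = {b: genome.sequence.count(b) for b in bases}
    counts = pd.DataFrame(0, index=bases, columns=list(callsets_by_group))
    for grp, callsets in callsets_by_group.items():
        for cs in callsets:
            for cls in classes:
                for v in cs.variants(cls):
                    counts.loc[genome.base_at(v.position), grp] += 1
    pct = counts.div(pd.Series(comp), axis=0) * 100.0
    if counts.to_numpy().sum() == 0:
        return BasePrevalence(counts, pct, None, None, skipped=True,
                              warning="no mutations in any group")
    # drop all-zero rows/columns so the chi-squared table is well-posed
    tab = counts.loc[counts.sum(axis=1) > 0, counts.sum(axis=0) > 0]
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return BasePrevalence(counts, pct, None, None, skipped=True,
                              warning="contingency table degenerate")
    chi2, p, _, expected = stats.chi2_contingency(tab.to_numpy())
    warning = "expected cell count below 1" if np.any(expected < 1) else ""
    return BasePrevalence(counts, pct, float(chi2), float(p), warning=warning)


# ---------------------------------------------------------------------------
# mtDNA copy number

def _usable(ct: Sequence[float] | None) -> np.ndarray | None:
    if ct is None:
        return None
    arr = np.asarray([v for v in ct if v is not None and math.isfinite(v)])
    return arr if arr.size >= 2 else None


def copy_number(
    ct_nuclear: Sequence[float] | None,
    ct_mito: Sequence[float] | None,
) -> float | None:
    """Relative mtDNA copy number ``2^(mean Ct_nDNA - mean Ct_mtDNA)``.

    Requires at least two usable replicates per target; otherwise the
    result is missing (None), not an exception.
    """
    nuc, mito = _usable(ct_nuclear), _usable(ct_mito)
    if nuc is None or mito is None:
        return None
    return float(2.0 ** (nuc.mean() - mito.mean()))


def mean_cq(ct_mito: Sequence[float] | None) -> float | None:
    """Mean mitochondrial Cq, reported for platelets (no nuclear DNA)."""
    mito = _usable(ct_mito)
    return None if mito is None else float(mito.mean())


# ---------------------------------------------------------------------------
# haplogroup flagging

@dataclass(frozen=True)
class HaplogroupCall:
    """A haplogroup *flag* from a packaged marker subset — an analysis aid
    for detecting group-composition confounding, never a clinical call."""

    subject_id: str
    label: str
    best_haplogroup: str
    matched_positions: tuple[int, ...]
    score: float
    scores: dict[str, float] = field(compare=False)


def load_marker_table(path: str | Path | None = None) -> dict[str, list[tuple[int, str]]]:
    """Packaged haplogroup marker subset: haplogroup -> [(np, alt base)]."""
    if path is None:
        path = Path(str(resources.files("mitorea").joinpath(
            "data", "haplogroup_markers.tsv")))
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[int, str]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.haplogroup, []).append((int(row.position), row.alt))
    return out


def haplogroup_assign(
    homoplasmic_variants: Iterable[tuple[int, str]],
    markers: Mapping[str, list[tuple[int, str]]] | None = None,
    subject_id: str = "",
    score_floor: float = 0.5,
) -> HaplogroupCall:
    """Best-scoring haplogroup from the packaged marker subset.

    Score = fraction of a haplogroup's markers present in the variant set;
    ties break lexicographically; below ``score_floor`` the label is
    'undetermined'; an empty variant set gets a reference-like label.
    """
    markers = markers if markers is not None else load_marker_table()
    variants = set((int(p), a) for p, a in homoplasmic_variants)
    scores = {}
    matched: dict[str, tuple[int, ...]] = {}
    for hg, mk in markers.items():
        hits = [p for p, a in mk if (p, a) in variants]
        scores[hg] = len(hits) / len(mk)
        matched[hg] = tuple(hits)
    best = min(scores, key=lambda h: (-scores[h], h))
    if not variants:
        return HaplogroupCall(subject_id, "rCRS-like", best, (), 0.0, scores)
    label = best if scores[best] >= score_floor else "undetermined"
    return HaplogroupCall(subject_id, label, best, matched[best],
                          scores[best], scores)


# ---------------------------------------------------------------------------
# Fisher's exact test with simulated p-value

@dataclass
class FisherResult:
    p: float
    n_sim: int
    degenerate: bool = False


def _log_table_prob(table: np.ndarray, lgam_margins: float, lgam_n: float) -> float:
    # log P(table | margins) = sum lg(r_i!) + sum lg(c_j!) - lg(N!) - sum lg(n_ij!)
    from scipy.special import gammaln
    return float(lgam_margins - lgam_n - gammaln(table + 1).sum())


def fisher_simulated(
    contingency_table: Sequence[Sequence[int]] | np.ndarray,
    n_sim: int = 10_000,
    seed: int = 0,
) -> FisherResult:
    """Fisher's exact test with a Monte-Carlo simulated p-value.

    Tables with the observed margins are sampled by random permutation of
    category labels; extremeness is measured by table probability under
    the fixed-margin (multivariate hypergeometric) null, and
    ``p = (1 + #{as or more extreme}) / (n_sim + 1)``.
    """
    from scipy.special import gammaln

    table = np.asarray(contingency_table, dtype=int)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("need a 2-D table of nonnegative integer counts")
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0) or table.sum() == 0:
        return FisherResult(1.0, 0, degenerate=True)

    n_total = int(table.sum())
    lgam_margins = gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
    lgam_n = gammaln(n_total + 1)
    logp_obs = _log_table_prob(table, lgam_margins, lgam_n)

    row_labels = np.repeat(np.arange(table.shape[0]), rows)
    col_labels = np.repeat(np.arange(table.shape[1]), cols)
    rng = np.random.default_rng(seed)
    n_rows, n_cols = table.shape
    hits = 0
    tol = 1e-9
    for _ in range(n_sim):
        perm = rng.permutation(col_labels)
        sim = np.zeros((n_rows, n_cols), dtype=int)
        np.add.at(sim, (row_labels, perm), 1)
        if _log_table_prob(sim, lgam_margins, lgam_n) <= logp_obs + tol:
            hits += 1
    return FisherResult((1 + hits) / (n_sim + 1), n_sim)


# ---------------------------------------------------------------------------
# correlation with normality gate

@dataclass
class CorrelationResult:
    method: str
    coefficient: float
    p: float
    n: int


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson or Spearman correlation behind a Lilliefors KS normality gate.

    Pairs with a missing member are dropped; both variables normal
    (Lilliefors p > 0.05) -> Pearson, otherwise Spearman.
    """
    x = np.asarray([math.nan if v is None else v for v in x], dtype=float)
    y = np.asarray([math.nan if v is None else v for v in y], dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 4:
        raise ValueError(f"need at least 4 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant variable")
    normal = (lilliefors(x, dist="norm")[1] > 0.05
              and lilliefors(y, dist="norm")[1] > 0.05)
    if normal:
        r, p = stats.pearsonr(x, y)
        return CorrelationResult("pearson", float(r), float(p), x.size)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult("spearman", float(rho), float(p), x.size)
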