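"""Seed-centric consensus correlation networks across cohorts.

Within each cohort dataset (disease samples only, by default) every
gene is correlated with the seed gene and flagged significant at
BH-adjusted p < 0.05 within that dataset.  A directional vote then
counts, per gene, the datasets with a significant positive correlation
(c+) and with a significant negative one (c-); the consensus
seed-centered correlation signature at threshold n, CGCCS(n), contains
the genes whose sign-consistent support max(c+, c-) reaches n.  Because
the rule thresholds a fixed count, CGCCS(n+1) is always nested inside
CGCCS(n).

The module also houses the seed-versus-trait utilities: gene-trait
correlations with pairwise-complete deletion, stratified variants, and
pairwise two-sample t-tests between severity groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, TraitTable
from .signatures import bh_adjust


# ---------------------------------------------------------------------------
# per-dataset seed correlations
# ---------------------------------------------------------------------------

def _corr_with_pvalues(M: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each row of M with y, plus two-sided t-test p-values."""
    n = y.size
    yc = y - y.mean()
    Mc = M - M.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.einsum("ij,ij->i", Mc, Mc) * float(yc @ yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Mc @ yc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    return r, p


def seed_correlations(
    expr: ExpressionMatrix,
    seed_gene: str,
    samples: list[str] | None = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Correlate every other gene with the seed on the selected samples.

    ``samples`` defaults to all columns; pipelines pass the disease
    subset.  BH adjustment is within the dataset.  Columns: ``dataset,
    gene, r, p, q, significant, sign``.
    """
    if seed_gene not in expr.values.index:
        raise ValueError(f"seed gene {seed_gene!r} not in expression matrix")
    values = expr.values if samples is None else expr.values.loc[:, list(samples)]
    y = values.loc[seed_gene].to_numpy(dtype=float)
    if y.std() == 0:
        raise ValueError("seed gene is constant on the selected samples")
    others = values.index[values.index != seed_gene]
    M = values.loc[others].to_numpy(dtype=float)
    r, p = _corr_with_pvalues(M, y)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "dataset": expr.dataset,
            "gene": others,
            "r": r,
            "p": p,
            "q": q,
            "significant": q < fdr_threshold,
            "sign": np.where(r >= 0, "+", "-"),
        }
    )


# ---------------------------------------------------------------------------
# directional voting and CGCCS
# ---------------------------------------------------------------------------

def directional_vote(records: pd.DataFrame) -> pd.DataFrame:
    """Tally signed significant correlations per gene across datasets.

    ``records`` stacks per-dataset :func:`seed_correlations` outputs; a
    gene absent from a dataset simply contributes no row there (the
    "na" cells).  Columns out: ``gene, c_pos, c_neg, n_datasets,
    frequency`` with frequency = max(c+, c-).
    """
    if records.duplicated(subset=["dataset", "gene"]).any():
        dup = records[records.duplicated(subset=["dataset", "gene"])]
        raise ValueError(
            f"duplicate (dataset, gene) records, e.g. {dup.iloc[0][['dataset','gene']].tolist()}"
        )
    sig = records["significant"].astype(bool)
    pos = sig & (records["sign"] == "+")
    neg = sig & (records["sign"] == "-")
    tally = (
        pd.DataFrame(
            {
                "gene": records["gene"],
                "c_pos": pos.astype(int),
                "c_neg": neg.astype(int),
                "n_datasets": 1,
            }
        )
        .groupby("gene", as_index=False)
        .sum()
    )
    tally["frequency"] = tally[["c_pos", "c_neg"]].max(axis=1)
    return tally.sort_values("gene", ignore_index=True)


@dataclass
class ConsensusNetwork:
    """CGCCS(n): genes supported by >= n datasets with a consistent sign."""

    seed_gene: str
    threshold: int
    members: pd.DataFrame  # columns: gene, sign in {+, -, ambiguous}
    n_datasets: int

    @property
    def genes(self) -> set[str]:
        return set(self.members["gene"])


def cgccs(
    tallies: pd.DataFrame,
    n: int,
    n_datasets: int,
    seed_gene: str = "seed",
    combined_counts: bool = False,
) -> ConsensusNetwork:
    """Membership at frequency threshold n.

    The default requires sign-consistent support (frequency =
    max(c+, c-)); ``combined_counts`` switches to c+ + c-.  Genes with
    c+ = c- >= n keep an ``ambiguous`` sign.
    """
    if not 1 <= n <= n_datasets:
        raise ValueError(f"threshold n={n} outside 1..{n_datasets}")
    freq = (
        tallies["c_pos"] + tallies["c_neg"]
        if combined_counts
        else tallies[["c_pos", "c_neg"]].max(axis=1)
    )
    keep = tallies[freq >= n]
    sign = np.where(
        keep["c_pos"] > keep["c_neg"],
        "+",
        np.where(keep["c_neg"] > keep["c_pos"], "-", "ambiguous"),
    )
    members = pd.DataFrame({"gene": keep["gene"], "sign": sign}).reset_index(drop=True)
    return ConsensusNetwork(
        seed_gene=seed_gene, threshold=n, members=members, n_datasets=n_datasets
    )


def correlation_long_table(records: pd.DataFrame, all_genes=None) -> pd.DataFrame:
    """Heatmap-ready long table with {**, *, ns, na} annotations.

    ``**``: q < 0.005; ``*``: q < 0.05; ``ns``: tested, not significant;
    ``na``: gene absent from that dataset (requires ``all_genes``).
    """
    out = records.copy()
    out["annotation"] = np.where(
        out["q"] < 0.005, "**", np.where(out["q"] < 0.05, "*", "ns")
    )
    out = out[["dataset", "gene", "r", "q", "annotation"]]
    if all_genes is not None:
        frames = [out]
        for ds, grp in out.groupby("dataset"):
            missing = sorted(set(all_genes) - set(grp["gene"]))
            if missing:
                frames.append(
                    pd.DataFrame(
                        {
                            "dataset": ds,
                            "gene": missing,
                            "r": np.nan,
                            "q": np.nan,
                            "annotation": "na",
                        }
                    )
                )
        out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["dataset", "gene"], ignore_index=True)


# ---------------------------------------------------------------------------
# trait correlations
# ---------------------------------------------------------------------------

def trait_correlation(
    expr: ExpressionMatrix,
    traits: TraitTable,
    genes: list[str],
    trait_names: list[str],
    method: str = "pearson",
) -> pd.DataFrame:
    """Gene-trait correlations with BH across the tested family.

    Missing trait values are handled by pairwise-complete deletion; a
    pair with fewer than 3 complete observations, or a constant trait,
    raises rather than silently returning zero.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    table = traits.table.loc[expr.samples]
    rows = []
    for gene in genes:
        x_full = expr.values.loc[gene].to_numpy(dtype=float)
        for trait in trait_names:
            if trait not in table.columns:
                raise ValueError(f"unknown trait {trait!r}")
            y_full = pd.to_numeric(table[trait], errors="raise").to_numpy(dtype=float)
            ok = ~np.isnan(y_full)
            x, y = x_full[ok], y_full[ok]
            if x.size < 3:
                raise ValueError(
                    f"fewer than 3 complete pairs for ({gene}, {trait})"
                )
            if np.std(y) == 0:
                raise ValueError(f"trait {trait!r} is constant on complete pairs")
            if np.std(x) == 0:
                raise ValueError(f"gene {gene!r} is constant on complete pairs")
            res = corr(x, y)
            rows.append((gene, trait, float(res.statistic), float(res.pvalue), x.size))
    out = pd.DataFrame(rows, columns=["gene", "trait", "r", "p", "n"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def stratified_correlation(
    expr: ExpressionMatrix,
    traits: TraitTable,
    gene: str,
    trait: str,
    strata: dict[str, list[str]],
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-stratum gene-trait correlation; small strata come back undefined.

    ``strata`` maps stratum name to sample ids; overlapping strata are
    rejected.  Columns: ``stratum, n, r, p, defined``.
    """
    seen: set[str] = set()
    for name, samples in strata.items():
        overlap = seen & set(samples)
        if overlap:
            raise ValueError(f"overlapping strata at {sorted(overlap)[:3]}")
        seen |= set(samples)
    rows = []
    for name, samples in strata.items():
        samples = [s for s in samples if s in expr.values.columns]
        try:
            sub = trait_correlation(
                expr.subset_samples(samples), traits.subset(samples),
                [gene], [trait], method,
            )
            rows.append((name, int(sub["n"].iloc[0]), float(sub["r"].iloc[0]),
                         float(sub["p"].iloc[0]), True))
        except ValueError:
            rows.append((name, len(samples), np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["stratum", "n", "r", "p", "defined"])


def standard_strata(traits: TraitTable, aod_cut: float = 85.0) -> dict[str, list[str]]:
    """Age / sex / APOE strata mirroring the usual AD stratified analyses."""
    t = traits.table
    strata: dict[str, list[str]] = {}
    if "AOD" in t.columns:
        strata[f"AOD>{aod_cut:g}"] = list(t.index[t["AOD"] > aod_cut])
        strata[f"AOD<={aod_cut:g}"] = list(t.index[t["AOD"] <= aod_cut])
    return strata


def severity_group_tests(
    expr: ExpressionMatrix,
    traits: TraitTable,
    gene: str,
    trait: str,
    min_group_size: int = 2,
) -> pd.DataFrame:
    """Pairwise two-sample t-tests of a gene across severity groups.

    Groups are the distinct values of the (discrete) trait; every group
    pair gets a Student t statistic and p, BH-adjusted across pairs.
    """
    t = traits.table.loc[expr.samples]
    values = expr.values.loc[gene]
    groups: dict = {}
    for level, idx in t.groupby(trait).groups.items():
        if len(idx) >= min_group_size:
            groups[level] = values.loc[idx].to_numpy(dtype=float)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups with enough samples")
    rows = []
    for a, b in combinations(sorted(groups), 2):
        xa, xb = groups[a], groups[b]
        if np.std(xa) == 0 and np.std(xb) == 0:
            raise ValueError(f"degenerate groups {a}, {b}")
        res = stats.ttest_ind(xa, xb)
        rows.append((a, b, len(xa), len(xb), float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "t", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
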