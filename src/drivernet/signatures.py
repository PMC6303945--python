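"""Differential-expression signatures, enrichment, and network projection.

DEG calling uses a two-sample t-test with optional empirical-Bayes
variance moderation: per-gene sample variances are shrunk toward a
pooled prior whose scale and degrees of freedom are estimated by moment
matching on the log variances, and the moderated t carries the combined
degrees of freedom.  A gene is a DEG when its linear-scale fold change
reaches the threshold (default 1.2-fold) and its BH-adjusted p-value is
below the cutoff (default 0.05).

Enrichment of one gene set in another within a finite universe is
reported as fold enrichment FE = (k/|A|)/(|B|/N) with a one-sided
(upper-tail) hypergeometric p-value, BH-adjusted across the tested
family.  Signature projection classifies each network gene into one of
eight categories by its membership in the up/down sets of the two
knockout contrasts (astrocyte-only and astrocyte+neuron co-culture).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values rejected; filter them before adjusting")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# moderated t / DEG calling
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if x <= 0:
            x = 1e-8
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of per-gene variances toward a pooled prior.

    Models s2 as scaled chi-square around a gene variance drawn from a
    scaled inverse chi-square prior with scale ``s0^2`` and ``d0``
    degrees of freedom, both estimated by matching the mean and variance
    of ``log s2``.  Returns (posterior variances, d0, s0^2); ``d0`` may
    be ``inf`` when the observed variances are essentially exchangeable.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    target = e_var - float(special.polygamma(1, df / 2.0))
    if target <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
        post = np.full_like(s2, s0_2)
        return post, d0, s0_2
    d0 = 2.0 * _trigamma_inverse(target)
    s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    post = (d0 * s0_2 + df * s2) / (d0 + df)
    return post, d0, s0_2


def call_degs(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    fc_threshold: float = 1.2,
    q_threshold: float = 0.05,
    moderated: bool = True,
    contrast: str = "A_vs_B",
) -> pd.DataFrame:
    """Per-gene differential expression of condition A over condition B.

    Expects log2-scale values on a shared gene universe; the fold-change
    gate applies on the linear scale (``|log2FC| >= log2(fc_threshold)``).
    Returns columns ``gene, log2fc, t, p, q, direction, significant,
    contrast``.
    """
    if list(expr_a.genes) != list(expr_b.genes):
        raise ValueError("mismatched gene universes between conditions")
    if expr_a.n_samples < 2 or expr_b.n_samples < 2:
        raise ValueError("need at least 2 samples per group")
    A = expr_a.values.to_numpy(dtype=float)
    Bv = expr_b.values.to_numpy(dtype=float)
    na, nb = A.shape[1], Bv.shape[1]
    df = na + nb - 2
    delta = A.mean(axis=1) - Bv.mean(axis=1)
    ssa = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((Bv - Bv.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = (ssa + ssb) / df
    if moderated:
        s2_post, d0, _ = squeeze_variances(s2, df)
        df_total = df + d0 if np.isfinite(d0) else np.inf
    else:
        s2_post, df_total = s2, df
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / se
    t = np.where(se == 0, np.where(delta == 0, 0.0, np.inf * np.sign(delta)), t)
    if np.isfinite(df_total):
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        p = 2.0 * stats.norm.sf(np.abs(t))
    q = bh_adjust(p)
    lfc_gate = np.abs(delta) >= np.log2(fc_threshold)
    out = pd.DataFrame(
        {
            "gene": expr_a.genes,
            "log2fc": delta,
            "t": t,
            "p": p,
            "q": q,
            "direction": np.where(delta > 0, "up", "dn"),
            "significant": lfc_gate & (q < q_threshold),
            "contrast": contrast,
        }
    )
    return out


def deg_sets(degs: pd.DataFrame, contrast: str | None = None) -> dict[str, set[str]]:
    """Split a DEG table into named up/down gene sets."""
    name = contrast or (degs["contrast"].iloc[0] if len(degs) else "DEG")
    sig = degs[degs["significant"]]
    return {
        f"{name}(up)": set(sig.loc[sig["direction"] == "up", "gene"]),
        f"{name}(dn)": set(sig.loc[sig["direction"] == "dn", "gene"]),
    }


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    query: str
    reference: str
    n_universe: int
    n_query: int
    n_reference: int
    overlap: int
    fold_enrichment: float
    p: float
    q: float | None = None

    def as_row(self) -> dict:
        return {
            "A": self.query,
            "B": self.reference,
            "N": self.n_universe,
            "k": self.overlap,
            "FE": self.fold_enrichment,
            "p": self.p,
            "q": self.q,
        }


def fisher_enrichment(
    a: set[str],
    b: set[str],
    universe: set[str],
    name_a: str = "A",
    name_b: str = "B",
) -> EnrichmentResult:
    """Fold enrichment and one-sided hypergeometric p for |A intersect B|."""
    a, b, universe = set(a), set(b), set(universe)
    if not a or not b:
        raise ValueError("fold enrichment undefined for empty query/reference set")
    if not a <= universe or not b <= universe:
        raise ValueError("query and reference sets must lie within the universe")
    n = len(universe)
    k = len(a & b)
    fe = (k / len(a)) / (len(b) / n)
    p = float(stats.hypergeom.sf(k - 1, n, len(b), len(a)))
    return EnrichmentResult(
        query=name_a,
        reference=name_b,
        n_universe=n,
        n_query=len(a),
        n_reference=len(b),
        overlap=k,
        fold_enrichment=fe,
        p=p,
    )


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Assemble results and BH-adjust across the tested family."""
    if not results:
        return pd.DataFrame(columns=["A", "B", "N", "k", "FE", "p", "q"])
    q = bh_adjust([r.p for r in results])
    for r, qv in zip(results, q):
        r.q = float(qv)
    return pd.DataFrame([r.as_row() for r in results])


def venn_counts(sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts for up to four sets.

    Keys are the tuples of set names a region belongs to; the empty
    region (elements in no set) is not reported.
    """
    if len(sets) > 4:
        raise ValueError("venn_counts supports at most 4 sets")
    names = list(sets)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo)) if combo else set()
            outside = set().union(*(sets[c] for c in names if c not in combo))
            counts[combo] = len(inside - outside)
    return counts


# ---------------------------------------------------------------------------
# signature sets and projection
# ---------------------------------------------------------------------------

@dataclass
class SignatureSet:
    """Named gene sets over a common background universe."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = set().union(*self.sets.values()) if self.sets else set()
        for name, members in self.sets.items():
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"set {name!r} has members outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


PROJECTION_CATEGORIES = (
    "AST-up-only",
    "AST-dn-only",
    "ASTNEU-up-only",
    "ASTNEU-dn-only",
    "both-up",
    "both-dn",
    "up-then-dn",
    "dn-then-up",
    "none",
)


def project_signatures(
    nodes,
    signatures: SignatureSet,
    ast_up: str = "AST(up)",
    ast_dn: str = "AST(dn)",
    astneu_up: str = "AST+NEU(up)",
    astneu_dn: str = "AST+NEU(dn)",
) -> tuple[pd.Series, pd.Series]:
    """Classify network nodes into the eight knockout-signature categories.

    ``up-then-dn`` marks genes up in the astrocyte-only contrast but
    down once neurons are co-cultured, and ``dn-then-up`` the converse.
    Returns (per-node labels, per-category counts over all categories).
    """
    au, ad = signatures[ast_up], signatures[ast_dn]
    nu, nd = signatures[astneu_up], signatures[astneu_dn]
    for name_u, name_d, u, d in ((ast_up, ast_dn, au, ad), (astneu_up, astneu_dn, nu, nd)):
        both = u & d
        if both:
            raise ValueError(
                f"genes in both {name_u} and {name_d}: {sorted(both)[:5]}"
            )
    labels = {}
    for gene in nodes:
        in_au, in_ad = gene in au, gene in ad
        in_nu, in_nd = gene in nu, gene in nd
        if in_au and in_nu:
            cat = "both-up"
        elif in_ad and in_nd:
            cat = "both-dn"
        elif in_au and in_nd:
            cat = "up-then-dn"
        elif in_ad and in_nu:
            cat = "dn-then-up"
        elif in_au:
            cat = "AST-up-only"
        elif in_ad:
            cat = "AST-dn-only"
        elif in_nu:
            cat = "ASTNEU-up-only"
        elif in_nd:
            cat = "ASTNEU-dn-only"
        else:
            cat = "none"
        labels[gene] = cat
    label_series = pd.Series(labels, name="category")
    counts = label_series.value_counts().reindex(PROJECTION_CATEGORIES, fill_value=0)
    return label_series, counts
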