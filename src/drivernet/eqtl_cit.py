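"""eQTL detection and the causal inference test (CIT) on locus trios.

A cis locus L that drives a mediator gene G which in turn drives a
target gene T leaves a testable signature: L associates with T, but
only through G.  The CIT formalises this as an intersection-union test
over four conditions for the chain ``L -> G -> T``:

1. T is associated with L;
2. G is associated with L given T;
3. T is associated with G given L;
4. T is independent of L given G.

Conditions 1-3 are nested-model F-tests on linear regressions (dosage
treated as an additive 0/1/2 covariate).  Condition 4 is an equivalence
test assessed by permutation: the fitted values of G on L are kept and
the residuals permuted, which preserves the L-G association while
breaking any mediation, and the conditional L-T statistic is recompared
against that null; a small observed statistic relative to the permuted
ones supports full mediation.  The omnibus p-value is the maximum of
the four components; both orientations (G mediates T, T mediates G) are
evaluated and a direction is called only when exactly one clears alpha.

Called directions, together with user-supplied TF->target edges, become
the structural priors for Bayesian network search.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GenotypeMatrix
from .signatures import bh_adjust

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# eQTL scan
# ---------------------------------------------------------------------------

def eqtl_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """F-test of expression on dosage for every (gene, locus) pair.

    Returns one row per tested pair with columns ``gene, locus, slope,
    F, p, q, significant``; BH adjustment spans all tested pairs and
    ``significant`` marks ``q < fdr_threshold``.  Monomorphic loci are
    skipped with a logged reason.
    """
    if expr.value_kind not in ("residual", "log"):
        raise ValueError("eQTL scan expects residual or log expression")
    geno = geno.aligned_to(expr)
    Y = expr.values.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=1, keepdims=True)
    n = Y.shape[1]
    rows = []
    for locus in geno.loci:
        g = geno.dosages.loc[locus].to_numpy(dtype=float)
        if (g == geno.missing_marker).any():
            raise ValueError(f"missing genotypes at {locus}; impute or drop first")
        g = g - g.mean()
        sxx = float(g @ g)
        if sxx == 0.0:
            logger.info("skipping monomorphic locus %s", locus)
            continue
        sxy = Y @ g
        slopes = sxy / sxx
        syy = np.einsum("ij,ij->i", Y, Y)
        rss = np.maximum(syy - slopes * sxy, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (slopes * sxy) / (rss / (n - 2))
        F = np.where(rss <= 0, np.inf, F)
        p = stats.f.sf(F, 1, n - 2)
        for gene, s, f_, p_ in zip(expr.genes, slopes, F, p):
            rows.append((gene, locus, float(s), float(f_), float(p_)))
    out = pd.DataFrame(rows, columns=["gene", "locus", "slope", "F", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] < fdr_threshold
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


# ---------------------------------------------------------------------------
# CIT
# ---------------------------------------------------------------------------

@dataclass
class CITResult:
    """Both-orientation CIT outcome for one (L, G, T) trio."""

    locus: str
    gene_g: str
    gene_t: str
    p_forward: tuple[float, float, float, float]  # G mediates: L->G->T
    p_reverse: tuple[float, float, float, float]  # T mediates: L->T->G
    omnibus_forward: float
    omnibus_reverse: float
    direction: str  # "G->T", "T->G" or "none"
    n_permutations: int

    def as_row(self) -> dict:
        return {
            "locus": self.locus,
            "G": self.gene_g,
            "T": self.gene_t,
            "omnibus_forward": self.omnibus_forward,
            "omnibus_reverse": self.omnibus_reverse,
            "direction": self.direction,
        }


def _f_added_last(y: np.ndarray, base: np.ndarray | None, added: np.ndarray) -> float:
    """F statistic for adding one centered regressor to a centered model."""
    n = y.size
    if base is None:
        X0 = np.empty((n, 0))
        rss0 = float(y @ y)
        k0 = 0
    else:
        X0 = base if base.ndim == 2 else base[:, None]
        b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
        r0 = y - X0 @ b0
        rss0 = float(r0 @ r0)
        k0 = X0.shape[1]
    X1 = np.column_stack([X0, added])
    b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    r1 = y - X1 @ b1
    rss1 = float(r1 @ r1)
    df = n - 1 - (k0 + 1)  # centered data: intercept already absorbed
    if rss1 <= 0:
        return np.inf
    return max(rss0 - rss1, 0.0) / (rss1 / df)


def _orientation_pvalues(
    l: np.ndarray,
    m: np.ndarray,
    y: np.ndarray,
    perm_idx: np.ndarray,
) -> tuple[float, float, float, float]:
    """Component p-values for the chain L -> m -> y (all inputs centered)."""
    n = l.size
    df2 = n - 3  # two regressors + intercept
    # 1: y ~ L
    p1 = float(stats.f.sf(_f_added_last(y, None, l), 1, n - 2))
    # 2: m ~ L | y
    p2 = float(stats.f.sf(_f_added_last(m, y, l), 1, df2))
    # 3: y ~ m | L
    p3 = float(stats.f.sf(_f_added_last(y, l, m), 1, df2))
    # 4: equivalence y _||_ L | m, by permutation of the residuals of m ~ L
    sll = float(l @ l)
    fit = (float(m @ l) / sll) * l
    resid = m - fit
    f_obs = _f_added_last(y, m, l)
    # vectorised F for L given m* = fit + permuted residuals
    R = resid[perm_idx]  # B x n
    Mstar = fit[None, :] + R
    syy = float(y @ y)
    sym = Mstar @ y
    sml = Mstar @ l
    smm = np.einsum("bj,bj->b", Mstar, Mstar)
    syl = float(y @ l)
    rss0 = syy - sym**2 / smm
    det = smm * sll - sml**2
    with np.errstate(divide="ignore", invalid="ignore"):
        b_m = (sll * sym - sml * syl) / det
        b_l = (smm * syl - sml * sym) / det
        rss1 = syy - (b_m * sym + b_l * syl)
        f_perm = np.maximum(rss0 - rss1, 0.0) / (rss1 / df2)
    f_perm = np.where(rss1 <= 0, np.inf, f_perm)
    B = perm_idx.shape[0]
    p4 = (1.0 + np.sum(f_perm <= f_obs)) / (B + 1.0)
    return p1, p2, p3, float(p4)


def cit_test(
    L: np.ndarray,
    G: np.ndarray,
    T: np.ndarray,
    B: int = 500,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    locus: str = "L",
    gene_g: str = "G",
    gene_t: str = "T",
) -> CITResult:
    """Run the four-condition CIT in both orientations for one trio.

    The same permutation index matrix serves both orientations, so
    swapping the roles of G and T swaps the two orientation results
    exactly.
    """
    L = np.asarray(L, dtype=float)
    G = np.asarray(G, dtype=float)
    T = np.asarray(T, dtype=float)
    if not (L.size == G.size == T.size):
        raise ValueError("L, G, T must be aligned vectors")
    if np.unique(L).size < 2:
        raise ValueError("dosage vector has fewer than 2 genotype classes")
    if G.std() == 0 or T.std() == 0:
        raise ValueError("degenerate (zero-variance) expression vector")
    if B < 100:
        warnings.warn(
            f"B={B} permutations is below the recommended minimum of 100",
            stacklevel=2,
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = L.size
    perm_idx = np.array([rng.permutation(n) for _ in range(B)])
    l = L - L.mean()
    g = G - G.mean()
    t = T - T.mean()
    p_fwd = _orientation_pvalues(l, g, t, perm_idx)
    p_rev = _orientation_pvalues(l, t, g, perm_idx)
    omni_fwd = max(p_fwd)
    omni_rev = max(p_rev)
    fwd_ok = omni_fwd < alpha
    rev_ok = omni_rev < alpha
    if fwd_ok and not rev_ok:
        direction = "G->T"
    elif rev_ok and not fwd_ok:
        direction = "T->G"
    else:
        direction = "none"
    return CITResult(
        locus=locus,
        gene_g=gene_g,
        gene_t=gene_t,
        p_forward=p_fwd,
        p_reverse=p_rev,
        omnibus_forward=omni_fwd,
        omnibus_reverse=omni_rev,
        direction=direction,
        n_permutations=B,
    )


def enumerate_trios(
    eqtl_hits: pd.DataFrame,
    max_pairs_per_locus: int | None = 200,
    p_threshold: float | None = 0.01,
) -> list[tuple[str, str, str]]:
    """All ordered (locus, G, T) trios of genes sharing an eQTL signal.

    Eligibility defaults to a raw association p < 0.01 per (gene, locus)
    pair rather than the scan's BH flag: trio enumeration is a casting
    step, and the four-condition test downstream provides the error
    control, so a permissive gate buys directed-prior coverage deep in
    regulatory cascades at no calibration cost.  Pass
    ``p_threshold=None`` to fall back to the scan's ``significant``
    column (BH q below its FDR threshold).
    """
    trios = []
    if p_threshold is None:
        sig = eqtl_hits[eqtl_hits["significant"]]
    else:
        sig = eqtl_hits[eqtl_hits["p"] < p_threshold]
    for locus, grp in sig.groupby("locus"):
        genes = sorted(grp["gene"])
        pairs = [(a, b) for i, a in enumerate(genes) for b in genes[i + 1 :]]
        if max_pairs_per_locus is not None:
            pairs = pairs[:max_pairs_per_locus]
        for a, b in pairs:
            trios.append((str(locus), a, b))
    return trios


def run_cit_for_trios(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    trios: list[tuple[str, str, str]],
    B: int = 500,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> list[CITResult]:
    geno = geno.aligned_to(expr)
    rng = np.random.default_rng(seed)
    results = []
    for locus, g_name, t_name in trios:
        L = geno.dosages.loc[locus].to_numpy(dtype=float)
        G = expr.values.loc[g_name].to_numpy(dtype=float)
        T = expr.values.loc[t_name].to_numpy(dtype=float)
        results.append(
            cit_test(L, G, T, B=B, alpha=alpha, rng=rng,
                     locus=locus, gene_g=g_name, gene_t=t_name)
        )
    return results


# ---------------------------------------------------------------------------
# structural priors
# ---------------------------------------------------------------------------

def build_priors(
    cit_results: list[CITResult],
    tf_edges: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    tf_weight: float = 0.8,
) -> pd.DataFrame:
    """Union of CIT-called edges and TF->target edges as a prior edge set.

    CIT edges weigh ``1 - omnibus p`` (an operational causal
    probability); TF edges carry a configured constant weight.
    Duplicates keep the maximum weight and the union of source tags.
    Columns: ``source, target, weight, tags``.
    """
    edges: dict[tuple[str, str], dict] = {}

    def add(source: str, target: str, weight: float, tag: str) -> None:
        if source == target:
            raise ValueError(f"self-edge rejected: {source}->{target}")
        if not 0.0 < weight <= 1.0:
            raise ValueError(f"prior weight must be in (0, 1]: {weight}")
        rec = edges.setdefault((source, target), {"weight": 0.0, "tags": set()})
        rec["weight"] = max(rec["weight"], weight)
        rec["tags"].add(tag)

    for res in cit_results:
        if res.direction == "G->T" and res.omnibus_forward < alpha:
            add(res.gene_g, res.gene_t, 1.0 - res.omnibus_forward, "CIT")
        elif res.direction == "T->G" and res.omnibus_reverse < alpha:
            add(res.gene_t, res.gene_g, 1.0 - res.omnibus_reverse, "CIT")
    for source, target in tf_edges or []:
        add(source, target, tf_weight, "TF")
    rows = [
        {
            "source": s,
            "target": t,
            "weight": rec["weight"],
            "tags": ",".join(sorted(rec["tags"])),
        }
        for (s, t), rec in sorted(edges.items())
    ]
    return pd.DataFrame(rows, columns=["source", "target", "weight", "tags"])
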