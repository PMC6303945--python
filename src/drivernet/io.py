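"""Readers and writers for the plain-text interchange formats.

Matrices are gene-major, tab-delimited, UTF-8.  Gene sets use the GMT
convention (name, description, members); networks are edge-list TSV or
SIF; genotypes travel as dosage TSV or a minimal diploid-GT VCF.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .datatypes import ExpressionMatrix, GenotypeMatrix, TraitTable

# -- expression ------------------------------------------------------------

def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")


def read_expression_tsv(path, value_kind: str = "log", dataset: str | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return ExpressionMatrix(df, value_kind, dataset or Path(path).stem)


# -- genotypes -------------------------------------------------------------

def write_genotype_tsv(geno: GenotypeMatrix, path) -> None:
    geno.dosages.to_csv(path, sep="\t", index_label="locus")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return GenotypeMatrix(df.astype(int))


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_minimal_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal VCF with a GT-only FORMAT field; dosage = ALT allele count."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", geno.missing_marker: "./."}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for pos, locus in enumerate(geno.loci, start=1):
            row = geno.dosages.loc[locus]
            gts = "\t".join(gt_map[int(v)] for v in row)
            fh.write(f"1\t{pos}\t{locus}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def read_minimal_vcf(path) -> GenotypeMatrix:
    """Read a diploid-GT VCF into an allele-dosage matrix (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    loci: list[str] = []
    rows: list[list[int]] = []
    for var in vcf:
        loci.append(var.ID or f"{var.CHROM}:{var.POS}")
        dosages = []
        for call in var.genotypes:
            alleles = call[:-1]  # last element is the phasing flag
            if any(a < 0 for a in alleles):
                dosages.append(-1)
            else:
                dosages.append(sum(1 for a in alleles if a > 0))
        rows.append(dosages)
    vcf.close()
    return GenotypeMatrix(pd.DataFrame(rows, index=loci, columns=samples))


# -- traits ----------------------------------------------------------------

def write_traits_csv(traits: TraitTable, path) -> None:
    traits.table.to_csv(path, index_label="sample")


def read_traits_csv(path) -> TraitTable:
    df = pd.read_csv(path, index_col=0)
    df.index.name = None
    return TraitTable(df)


# -- gene sets (GMT) -------------------------------------------------------

def write_gmt(sets: dict[str, set[str] | list[str]], path, description: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            row = [name, description or name] + sorted(members)
            fh.write("\t".join(row) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            sets[fields[0]] = set(f for f in fields[2:] if f)
    return sets


# -- networks --------------------------------------------------------------

def write_edge_tsv(graph: nx.DiGraph, path, weight: str = "weight") -> None:
    rows = [
        {"source": u, "target": v, "weight": d.get(weight, 1.0)}
        for u, v, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_tsv(path) -> nx.DiGraph:
    df = pd.read_csv(path, sep="\t")
    g = nx.DiGraph()
    for row in df.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight))
    return g


def write_sif(graph: nx.DiGraph, path, relation: str = "regulates") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{relation}\t{v}\n")
        for node in sorted(graph.nodes()):
            if graph.degree(node) == 0:
                fh.write(f"{node}\n")


def read_sif(path) -> nx.DiGraph:
    g = nx.DiGraph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                g.add_edge(fields[0], fields[2])
            elif len(fields) == 1 and fields[0]:
                g.add_node(fields[0])
    return g


# -- prior edges -----------------------------------------------------------

def write_prior_tsv(priors: pd.DataFrame, path) -> None:
    priors.to_csv(path, sep="\t", index=False)


def read_tf_edges(path) -> list[tuple[str, str]]:
    """Two-column (TF, target) TSV; extra columns ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return [(str(r[0]), str(r[1])) for r in df.itertuples(index=False)]
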