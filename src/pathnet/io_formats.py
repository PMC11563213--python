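"""Readers, writers and in-memory domain types for every external file format.

All downstream modules operate on the domain types defined here
(:class:`GenotypeDataset`, :class:`PPINetwork`, :class:`PathwayCollection`,
:class:`GeneScoreTable`, :class:`SnpGeneMap`); no other module parses files.

File dialects (all plain TSV, no compression):

* genotype matrix — rows = samples, header = SNP ids, cells in {0, 1, 2, NA}
* SNP map — columns ``snp_id``, ``chrom``, ``pos``
* phenotype table — columns ``sample_id``, ``status`` (``case``/``control``)
* score table — columns ``gene``, ``pvalue``
* SNP→gene map — columns ``snp_id``, ``gene_id``, ``priority_score``
* PPI edge list — two whitespace/tab-separated columns, SIF three-column
  dialect (``A pp B``) tolerated
* pathway collections — standard GMT (id, description, member genes)

Gene identifiers are opaque strings throughout; no symbol/Entrez translation
is attempted (the user's mapping files define the namespace).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: genotype codes: 0 = ref-hom, 1 = het, 2 = alt-hom; missing is np.nan
VALID_GENOTYPE_CODES = {"0", "1", "2"}
MISSING_CODES = {"NA", "NaN", "nan", ""}

#: chromosome labels (lower-cased) treated as the Y chromosome
Y_CHROM_LABELS = {"y", "chry", "24"}


class ParseError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """A parsed file violates a cross-file or domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeDataset:
    """Samples × SNPs genotype matrix with SNP annotation and phenotypes.

    ``genotypes`` is a float array of shape ``(n_samples, n_snps)`` holding
    codes {0, 1, 2} with ``nan`` for missing calls.  ``phenotypes`` holds
    ``"case"`` / ``"control"`` per sample.
    """

    sample_ids: list[str]
    phenotypes: np.ndarray
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.phenotypes = np.asarray(self.phenotypes, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        n_samples, n_snps = len(self.sample_ids), len(self.snp_ids)
        if self.genotypes.shape != (n_samples, n_snps):
            raise ValidationError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{n_samples} samples x {n_snps} SNPs"
            )
        if len(self.phenotypes) != n_samples:
            raise ValidationError("one phenotype required per sample")
        bad = set(self.phenotypes) - {"case", "control"}
        if bad:
            raise ValidationError(f"unknown phenotype labels: {sorted(bad)}")
        if len(self.chrom) != n_snps or len(self.pos) != n_snps:
            raise ValidationError("chrom/pos annotation must cover every SNP")
        if np.any(self.pos <= 0):
            raise ValidationError("SNP positions must be positive")
        if len(set(self.snp_ids)) != n_snps:
            raise ValidationError("snp_ids must be unique")
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("sample_ids must be unique")
        with np.errstate(invalid="ignore"):
            codes_ok = np.isnan(self.genotypes) | np.isin(self.genotypes, (0.0, 1.0, 2.0))
        if not codes_ok.all():
            raise ValidationError("genotype codes must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def is_case(self) -> np.ndarray:
        return self.phenotypes == "case"

    def is_y_chrom(self) -> np.ndarray:
        """Boolean mask of SNPs on the Y chromosome (label set documented)."""
        return np.array([str(c).lower() in Y_CHROM_LABELS for c in self.chrom])

    def subset_snps(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeDataset(
            sample_ids=self.sample_ids,
            phenotypes=self.phenotypes,
            snp_ids=[self.snp_ids[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            genotypes=self.genotypes[:, idx],
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeDataset":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypeDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            phenotypes=self.phenotypes[idx],
            snp_ids=self.snp_ids,
            chrom=self.chrom,
            pos=self.pos,
            genotypes=self.genotypes[idx, :],
        )


@dataclass
class PPINetwork:
    """Undirected simple protein–protein interaction graph."""

    nodes: set[str]
    edges: set[frozenset]

    def __post_init__(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValidationError(f"self-loop or malformed edge: {set(e)}")
            if not e <= self.nodes:
                raise ValidationError(f"edge endpoint not a node: {set(e)}")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(tuple(sorted(e)) for e in self.edges))
        return g

    @classmethod
    def from_networkx(cls, g) -> "PPINetwork":
        return cls(
            nodes=set(g.nodes()),
            edges={frozenset((u, v)) for u, v in g.edges() if u != v},
        )


@dataclass
class PathwayRecord:
    pathway_id: str
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValidationError(f"pathway {self.pathway_id}: empty gene set")


@dataclass
class PathwayCollection:
    records: list[PathwayRecord]

    def __post_init__(self) -> None:
        ids = [r.pathway_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate pathway ids: {dup}")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, pathway_id: str) -> PathwayRecord:
        for r in self.records:
            if r.pathway_id == pathway_id:
                return r
        raise KeyError(pathway_id)

    @property
    def ids(self) -> list[str]:
        return [r.pathway_id for r in self.records]


@dataclass
class GeneScoreTable:
    """Gene → p-value table for one omics layer (genomic or proteomic)."""

    entries: dict[str, float]
    layer_label: str

    def __post_init__(self) -> None:
        if self.layer_label not in ("genomic", "proteomic"):
            raise ValidationError(f"unknown layer label: {self.layer_label}")
        for gene, p in self.entries.items():
            if not (0.0 < p <= 1.0) or math.isnan(p):
                raise ValidationError(f"p-value for {gene} outside (0, 1]: {p}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SnpGeneMap:
    """SNP → candidate gene rows with functional-priority scores.

    Larger ``priority_score`` means a more important functional effect;
    a SNP may map to several candidate genes.
    """

    rows: pd.DataFrame  # columns: snp_id, gene_id, priority_score

    def __post_init__(self) -> None:
        required = ["snp_id", "gene_id", "priority_score"]
        if list(self.rows.columns[:3]) != required:
            raise ValidationError(f"SNP-gene map columns must be {required}")
        if not np.isfinite(self.rows["priority_score"].to_numpy(float)).all():
            raise ValidationError("priority scores must be finite")
        if self.rows.duplicated(subset=["snp_id", "gene_id"]).any():
            raise ValidationError("duplicate (snp_id, gene_id) pairs")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_gmt(path) -> PathwayCollection:
    """Read a GMT gene-set file (one pathway per line: id, name, genes...).

    Duplicate genes within a line are deduplicated; a line with fewer than
    three fields or a repeated pathway id is an error.
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            pid, name, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ParseError(f"{path}: line {lineno}: pathway {pid} has no genes")
            records.append(PathwayRecord(pid, name, frozenset(genes)))
    return PathwayCollection(records)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for rec in collection:
            fh.write("\t".join([rec.pathway_id, rec.name, *sorted(rec.genes)]) + "\n")


def read_edge_list(path) -> PPINetwork:
    """Read a PPI edge list (two-column TSV; SIF ``A pp B`` tolerated).

    Self-loops are dropped and duplicate / reversed-duplicate edges collapsed;
    every drop is counted and logged.
    """
    nodes: set[str] = set()
    edges: set[frozenset] = set()
    n_self, n_dup = 0, 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: need >=2 columns")
            if len(fields) == 3:
                a, _interaction, b = fields  # SIF dialect
            else:
                a, b = fields[0], fields[1]
            nodes.update((a, b))
            if a == b:
                n_self += 1
                continue
            e = frozenset((a, b))
            if e in edges:
                n_dup += 1
            edges.add(e)
    if n_self or n_dup:
        logger.warning(
            "%s: dropped %d self-loop(s), collapsed %d duplicate edge(s)",
            path, n_self, n_dup,
        )
    return PPINetwork(nodes=nodes, edges=edges)


def write_edge_list(ppi: PPINetwork, path) -> None:
    with open(path, "w") as fh:
        for e in sorted(tuple(sorted(x)) for x in ppi.edges):
            fh.write(f"{e[0]}\t{e[1]}\n")
        # isolated nodes are not representable in an edge list; drop silently
        isolated = ppi.nodes - {n for e in ppi.edges for n in e}
        if isolated:
            logger.warning("%s: %d isolated node(s) not written", path, len(isolated))


def _parse_genotype_cell(cell: str, path, lineno: int) -> float:
    cell = cell.strip()
    if cell in MISSING_CODES:
        return np.nan
    if cell in VALID_GENOTYPE_CODES:
        return float(cell)
    raise ParseError(f"{path}: line {lineno}: invalid genotype code {cell!r}")


def read_genotypes(genotype_path, snpmap_path, phenotype_path) -> GenotypeDataset:
    """Read and cross-validate genotype matrix + SNP map + phenotype table.

    SNP order follows the genotype header.  Every sample must appear in the
    phenotype file and every SNP in the map file.
    """
    with open(genotype_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{genotype_path}: header needs sample column + >=1 SNP")
        snp_ids = header[1:]
        sample_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            cells = raw.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise ParseError(
                    f"{genotype_path}: line {lineno}: expected "
                    f"{len(header)} columns, got {len(cells)}"
                )
            sample_ids.append(cells[0])
            rows.append(
                [_parse_genotype_cell(c, genotype_path, lineno) for c in cells[1:]]
            )

    snpmap = pd.read_csv(snpmap_path, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in ("snp_id", "chrom", "pos"):
        if col not in snpmap.columns:
            raise ParseError(f"{snpmap_path}: missing column {col!r}")
    snpmap = snpmap.set_index("snp_id")
    missing_snps = [s for s in snp_ids if s not in snpmap.index]
    if missing_snps:
        raise ValidationError(
            f"{len(missing_snps)} SNP(s) in genotype header missing from map, "
            f"first: {missing_snps[0]}"
        )
    snpmap = snpmap.loc[snp_ids]

    pheno = pd.read_csv(phenotype_path, sep="\t", dtype=str)
    for col in ("sample_id", "status"):
        if col not in pheno.columns:
            raise ParseError(f"{phenotype_path}: missing column {col!r}")
    pheno = pheno.set_index("sample_id")["status"]
    missing_samples = [s for s in sample_ids if s not in pheno.index]
    if missing_samples:
        raise ValidationError(
            f"sample(s) absent from phenotype file: {missing_samples[:5]}"
        )

    return GenotypeDataset(
        sample_ids=sample_ids,
        phenotypes=pheno.loc[sample_ids].to_numpy(dtype=object),
        snp_ids=snp_ids,
        chrom=snpmap["chrom"].to_numpy(dtype=object),
        pos=snpmap["pos"].to_numpy(dtype=np.int64),
        genotypes=np.array(rows, dtype=float).reshape(len(sample_ids), len(snp_ids)),
    )


def write_genotypes(dataset: GenotypeDataset, genotype_path, snpmap_path,
                    phenotype_path) -> None:
    """Write a GenotypeDataset back to the three-file TSV dialect."""
    with open(genotype_path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(dataset.snp_ids) + "\n")
        for i, sid in enumerate(dataset.sample_ids):
            cells = [
                "NA" if np.isnan(g) else str(int(g)) for g in dataset.genotypes[i]
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")
    pd.DataFrame(
        {"snp_id": dataset.snp_ids, "chrom": dataset.chrom, "pos": dataset.pos}
    ).to_csv(snpmap_path, sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": dataset.sample_ids, "status": dataset.phenotypes}
    ).to_csv(phenotype_path, sep="\t", index=False)


def read_score_table(path, layer_label: str) -> GeneScoreTable:
    """Read a two-column (gene, pvalue) TSV into a GeneScoreTable."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "pvalue"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if df["gene"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene rows")
    return GeneScoreTable(
        entries=dict(zip(df["gene"], df["pvalue"].astype(float))),
        layer_label=layer_label,
    )


def write_score_table(table: GeneScoreTable, path) -> None:
    df = pd.DataFrame(
        sorted(table.entries.items()), columns=["gene", "pvalue"]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_snp_gene_map(path) -> SnpGeneMap:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str})
    for col in ("snp_id", "gene_id", "priority_score"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    return SnpGeneMap(rows=df[["snp_id", "gene_id", "priority_score"]])


def write_snp_gene_map(snpmap: SnpGeneMap, path) -> None:
    snpmap.rows.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# results writer
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "pathway_id", "pathway_name", "p_genomic", "p_proteomic", "p_final",
    "cluster", "representative", "genes", "snps",
]


def write_results(merged_results, cluster_assignment, path) -> pd.DataFrame:
    """Write the final pathway report (one row per merged enriched pathway).

    Rows are sorted by ascending final p-value, ties broken by pathway id;
    numeric columns are written with 12 significant digits so a re-read
    reproduces them.  Returns the DataFrame written.
    """
    rows = []
    for r in merged_results:
        cluster = rep = None
        if cluster_assignment is not None and r.pathway_id in cluster_assignment.labels:
            cluster = cluster_assignment.labels[r.pathway_id]
            rep = r.pathway_id in cluster_assignment.representatives
        rows.append({
            "pathway_id": r.pathway_id,
            "pathway_name": r.name,
            "p_genomic": r.p_genomic,
            "p_proteomic": r.p_proteomic,
            "p_final": r.p_final,
            "cluster": cluster,
            "representative": rep,
            "genes": ";".join(sorted(r.genes)),
            "snps": ";".join(sorted(r.snps)),
        })
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df = df.sort_values(["p_final", "pathway_id"], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return df


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"pathway_id": str})
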