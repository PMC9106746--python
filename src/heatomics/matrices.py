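"""Core in-memory containers and TSV/GFF3/CSV readers.

All tabular formats are plain TSV with a header row, UTF-8, '.' decimal.
Proteome matrices encode missing values as empty cells (or 0), matching
common label-free quantification exports. Gene lengths may come from a
two-column TSV or from a GFF3, where the length of a gene is the size of
the union of its exon intervals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "TpmMatrix",
    "ProteomeMatrix",
    "OntologyAnnotation",
    "KineticTrace",
    "read_counts",
    "read_gene_lengths",
    "read_proteome",
    "read_ontology",
    "read_trace_csv",
]


class MatrixFormatError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene-level integer counts (genes x samples) with gene lengths in bp."""

    counts: pd.DataFrame = field(repr=False)
    gene_length_bp: pd.Series = field(repr=False)

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise MatrixFormatError(f"duplicate gene ids: {dup}")
        missing = self.counts.index.difference(self.gene_length_bp.index)
        if len(missing):
            raise MatrixFormatError(
                f"genes without a length entry: {list(missing)}"
            )
        self.gene_length_bp = self.gene_length_bp.loc[self.counts.index].astype(float)
        if (self.gene_length_bp <= 0).any():
            bad = self.gene_length_bp.index[self.gene_length_bp <= 0].tolist()
            raise MatrixFormatError(f"non-positive gene lengths: {bad}")
        if (self.counts.to_numpy() < 0).any():
            raise MatrixFormatError("negative counts")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        keep = self.counts.index.intersection(pd.Index(gene_ids))
        return ExpressionMatrix(self.counts.loc[keep], self.gene_length_bp.loc[keep])

    def write(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length_bp", self.gene_length_bp)
        out.to_csv(path, sep="\t", index_label="gene_id")

    @staticmethod
    def read(path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        lengths = df.pop("length_bp")
        return ExpressionMatrix(df.astype(np.int64), lengths)


@dataclass
class TpmMatrix:
    """Transcripts-per-million matrix; every column sums to 1e6."""

    tpm: pd.DataFrame = field(repr=False)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    def write(self, path) -> None:
        self.tpm.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class ProteomeMatrix:
    """Protein-group intensities with an explicit missingness mask.

    ``intensities`` holds NaN where unobserved; ``proteotypic`` flags groups
    quantified only from peptides unique to a single protein. Group ids may
    list several members separated by ';'.
    """

    intensities: pd.DataFrame = field(repr=False)
    proteotypic: pd.Series = field(repr=False, default=None)
    imputed_mask: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self):
        if self.intensities.index.duplicated().any():
            raise MatrixFormatError("duplicate protein group ids")
        vals = self.intensities.to_numpy()
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise MatrixFormatError("observed intensities must be strictly positive")
        if self.proteotypic is None:
            self.proteotypic = pd.Series(True, index=self.intensities.index)
        else:
            self.proteotypic = self.proteotypic.loc[self.intensities.index].astype(bool)
        if self.imputed_mask is None:
            self.imputed_mask = pd.DataFrame(
                False, index=self.intensities.index, columns=self.intensities.columns
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.intensities.isna()

    def write(self, path) -> None:
        out = self.intensities.copy()
        out.insert(0, "proteotypic", self.proteotypic.astype(int))
        out.to_csv(path, sep="\t", index_label="protein_id", na_rep="")

    @staticmethod
    def read(path) -> "ProteomeMatrix":
        df = pd.read_csv(path, sep="\t", index_col="protein_id")
        if "proteotypic" in df.columns:
            proteo = df.pop("proteotypic").astype(bool)
        else:
            proteo = None
        df = df.astype(float)
        df = df.where(df > 0)  # blanks and zeros are missing
        return ProteomeMatrix(df, proteo)


@dataclass
class OntologyAnnotation:
    """MapMan-bin style term forest plus entity -> term assignments."""

    terms: pd.DataFrame = field(repr=False)  # term_id, name, parent ('' = root)
    assignments: dict = field(repr=False)  # entity_id -> set of term ids

    def __post_init__(self):
        if "term_id" in self.terms.columns:
            self.terms = self.terms.set_index("term_id")
        known = set(self.terms.index)
        for parent in self.terms["parent"]:
            if parent and parent not in known:
                raise MatrixFormatError(f"parent term {parent!r} not in tree")
        self._check_acyclic()
        for ent, ts in self.assignments.items():
            bad = set(ts) - known
            if bad:
                raise MatrixFormatError(
                    f"entity {ent} assigned to unknown terms {sorted(bad)}"
                )

    def _check_acyclic(self):
        parent = self.terms["parent"].to_dict()
        for start in parent:
            seen = set()
            node = start
            while node:
                if node in seen:
                    raise MatrixFormatError(f"cycle in term tree at {node!r}")
                seen.add(node)
                node = parent.get(node, "")

    def ancestors(self, term_id: str) -> list[str]:
        """The term itself followed by its ancestors up to the root."""
        chain = []
        node = term_id
        parent = self.terms["parent"]
        while node:
            chain.append(node)
            node = parent.get(node, "")
        return chain

    def expanded(self, entity_id: str) -> set[str]:
        """Tree-expanded term set: every assigned term plus all ancestors."""
        out: set[str] = set()
        for t in self.assignments.get(entity_id, ()):
            out.update(self.ancestors(t))
        return out

    def write(self, terms_path, assign_path) -> None:
        self.terms.to_csv(terms_path, sep="\t", index_label="term_id")
        rows = [
            (ent, term)
            for ent, ts in sorted(self.assignments.items())
            for term in sorted(ts)
        ]
        pd.DataFrame(rows, columns=["entity_id", "term_id"]).to_csv(
            assign_path, sep="\t", index=False
        )


def read_ontology(terms_path, assign_path) -> OntologyAnnotation:
    terms = pd.read_csv(terms_path, sep="\t", dtype=str).fillna("")
    assign = pd.read_csv(assign_path, sep="\t", dtype=str)
    mapping: dict[str, set] = {}
    for ent, term in zip(assign["entity_id"], assign["term_id"]):
        mapping.setdefault(ent, set()).add(term)
    return OntologyAnnotation(terms, mapping)


TRACE_KINDS = ("od680", "fluorescence", "ecs", "p700", "o2", "spectrum77k", "facs_hist")


@dataclass
class KineticTrace:
    """A (x, y) instrument series: time in s/h, wavelength in nm, or
    fluorescence bins, depending on ``kind``. ``meta`` carries acquisition
    parameters such as actinic light intensity (umol photons m-2 s-1)."""

    kind: str
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in TRACE_KINDS:
            raise MatrixFormatError(f"unknown trace kind {self.kind!r}")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise MatrixFormatError("x and y lengths differ")
        if self.x.size and np.any(np.diff(self.x) <= 0):
            raise MatrixFormatError("x must be strictly increasing")

    def write(self, path) -> None:
        pd.DataFrame({"x": self.x, "y": self.y}).to_csv(path, index=False)


def read_trace_csv(path, kind: str, meta: dict | None = None) -> KineticTrace:
    df = pd.read_csv(path)
    x, y = df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
    return KineticTrace(kind, x, y, dict(meta or {}))


def read_gene_lengths(path) -> pd.Series:
    """Gene lengths from a TSV (gene_id, length_bp) or a GFF3.

    For GFF3 input the length of a gene is the number of bases covered by
    the union of its exons (1-based inclusive coordinates; overlapping
    exons are merged).
    """
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return _lengths_from_gff3(path)
    df = pd.read_csv(path, sep="\t")
    return pd.Series(
        df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str), name="length_bp"
    )


def _lengths_from_gff3(path) -> pd.Series:
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    lengths = {}
    for gene in db.features_of_type("gene"):
        exons = list(db.children(gene, featuretype="exon"))
        if not exons:
            exons = list(db.children(gene, featuretype="CDS")) or [gene]
        # convert 1-based inclusive to half-open, merge, sum
        iv = sorted((e.start - 1, e.end) for e in exons)
        total, cur_s, cur_e = 0, iv[0][0], iv[0][1]
        for s, e in iv[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += cur_e - cur_s
        lengths[gene.id] = float(total)
    return pd.Series(lengths, name="length_bp")


def read_counts(path, lengths) -> ExpressionMatrix:
    """Read a gene x sample TSV of integer counts and join gene lengths.

    ``lengths`` is a path (TSV or GFF3) or a pre-loaded Series. Non-integer
    cells raise a parse error naming the offending gene and sample; genes
    absent from the length table raise an error listing their ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        flt = df.astype(float).to_numpy()
        bad = np.argwhere(flt != np.floor(flt))
        if len(bad):
            g, s = bad[0]
            raise MatrixFormatError(
                f"non-integer count {df.iat[g, s]!r} at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}"
            )
        df = df.astype(np.int64)
    if isinstance(lengths, (str, bytes)) or hasattr(lengths, "__fspath__"):
        lengths = read_gene_lengths(lengths)
    missing = df.index.difference(lengths.index)
    if len(missing):
        raise MatrixFormatError(f"genes without a length entry: {list(missing)}")
    return ExpressionMatrix(df, lengths.loc[df.index])
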