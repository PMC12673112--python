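"""Count-matrix containers, I/O, gene annotation, QC filters and normalization.

The containers are deliberately thin wrappers around pandas objects:

* :class:`CountMatrix` — genes x observations UMI counts plus an
  observation-metadata table (``role`` in {wash, biopsy, cell, pixel},
  optional group label, optional spatial coordinates in micrometres).
* :class:`GeneAnnotation` — per-gene biotype and mitochondrial/ribosomal
  flags, plus named gene sets (e.g. an apoptosis set loaded from GMT).
* :class:`NormalizedMatrix` — per-observation expression fractions over a
  stated gene subset; observations with zero counts on the subset are
  flagged (masked with NaN), never silently divided.

All QC thresholds follow the conventions used throughout the package:
"more than N" and "above x" are strict inequalities, "below x" is strict,
and "ranging from a to b" is inclusive on both ends.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger("shedmap")

ROLES = ("wash", "biopsy", "cell", "pixel")

#: default thresholds, mirrored by the CLI config
DEFAULT_BULK_MIN_UMI = 10_000
DEFAULT_CELL_UMI_MIN = 1_500
DEFAULT_CELL_UMI_MAX = 10_000
DEFAULT_MAX_MITO_FRACTION = 0.5
DEFAULT_PIXEL_MIN_UMI = 20


class ShedmapError(Exception):
    """Base class for all shedmap errors."""


class ValidationError(ShedmapError):
    """Raised when an input violates a container invariant."""


class ParameterError(ShedmapError):
    """Raised on invalid parameter combinations."""


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Per-gene annotation: biotype, mito/ribo flags and named gene sets.

    ``table`` is indexed by gene id with boolean columns
    ``protein_coding``, ``is_mitochondrial``, ``is_ribosomal``.
    Gene identifiers are opaque strings; nothing here assumes a naming
    scheme except the optional :meth:`from_prefixes` convenience builder.
    """

    table: pd.DataFrame
    gene_sets: dict[str, frozenset] = field(default_factory=dict)

    REQUIRED = ("protein_coding", "is_mitochondrial", "is_ribosomal")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate gene identifiers in annotation")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"annotation missing column {col!r}")

    def for_genes(self, genes: Sequence[str]) -> pd.DataFrame:
        """Annotation rows aligned to ``genes``.

        Unannotated genes default to non-protein-coding / non-mito /
        non-ribo and are reported through the logger, so a gene that never
        resolves is dropped (not kept) by a protein-coding filter.
        """
        missing = pd.Index(genes).difference(self.table.index)
        if len(missing):
            logger.warning(
                "%d genes without annotation default to non-protein-coding "
                "(first few: %s)", len(missing), list(missing[:5])
            )
        out = self.table.reindex(genes)
        for col in self.REQUIRED:
            out[col] = out[col].eq(True)  # NaN (unannotated) -> False
        return out

    def gene_set(self, name: str) -> frozenset:
        try:
            return self.gene_sets[name]
        except KeyError:
            raise ParameterError(f"unknown gene set {name!r}") from None

    @classmethod
    def from_prefixes(cls, genes: Sequence[str],
                      mito_prefix: str = "MT-",
                      ribo_prefixes: tuple[str, ...] = ("RPL", "RPS"),
                      ) -> "GeneAnnotation":
        """Convenience builder assuming human-style symbols.

        Every gene is taken as protein-coding; mito/ribo status comes from
        the standard symbol prefixes (case-insensitive, so mouse ``mt-`` /
        ``Rpl``/``Rps`` symbols work too). Use a real annotation table
        whenever one is available.
        """
        idx = pd.Index(genes)
        upper = idx.str.upper()
        tab = pd.DataFrame(
            {
                "protein_coding": True,
                "is_mitochondrial": upper.str.startswith(mito_prefix.upper()),
                "is_ribosomal": upper.str.startswith(
                    tuple(p.upper() for p in ribo_prefixes)),
            },
            index=idx,
        )
        return cls(tab)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneAnnotation":
        """Read a TSV with columns gene_id, biotype, is_mito, is_ribo."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        tab = pd.DataFrame(
            {
                "protein_coding": df["biotype"].astype(str) == "protein_coding",
                "is_mitochondrial": df["is_mito"].astype(bool),
                "is_ribosomal": df["is_ribo"].astype(bool),
            },
            index=df.index.astype(str),
        )
        return cls(tab)

    def add_gene_set_gmt(self, path: str | Path) -> None:
        """Load gene sets from a GMT file (name, description, genes...)."""
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValidationError(f"malformed GMT line: {line[:80]!r}")
            self.gene_sets[parts[0]] = frozenset(g for g in parts[2:] if g)


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Genes x observations UMI count matrix with observation metadata.

    ``values``: DataFrame (rows genes, columns observations), counts >= 0.
    ``obs_meta``: DataFrame indexed by observation; recognised columns are
    ``role``, ``group``, ``x_um``, ``y_um``.
    """

    values: pd.DataFrame
    obs_meta: pd.DataFrame | None = None
    gene_meta: GeneAnnotation | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:3]
            raise ValidationError(f"duplicate gene identifiers: {list(dup)}")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate observation identifiers")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValidationError("non-finite count values")
        if (arr < 0).any():
            raise ValidationError("negative count values")
        if self.obs_meta is None:
            self.obs_meta = pd.DataFrame(index=self.values.columns)
        else:
            if not self.obs_meta.index.equals(self.values.columns):
                self.obs_meta = self.obs_meta.reindex(self.values.columns)
        if "role" in self.obs_meta:
            bad = set(self.obs_meta["role"].dropna()) - set(ROLES)
            if bad:
                raise ValidationError(f"unknown roles: {sorted(bad)}")
            pix = self.obs_meta["role"] == "pixel"
            if pix.any():
                for c in ("x_um", "y_um"):
                    if c not in self.obs_meta:
                        raise ValidationError(
                            "pixel observations require x_um/y_um coordinates")
                    coords = self.obs_meta.loc[pix, c].to_numpy(float)
                    if not np.all(np.isfinite(coords)):
                        raise ValidationError(f"non-finite pixel {c}")

    # -- convenience -------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def obs(self) -> pd.Index:
        return self.values.columns

    def totals(self) -> pd.Series:
        """Per-observation total UMI counts."""
        return self.values.sum(axis=0)

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.values.loc[list(genes)], self.obs_meta,
                           self.gene_meta)

    def subset_obs(self, obs: Sequence[str]) -> "CountMatrix":
        obs = list(obs)
        return CountMatrix(self.values[obs], self.obs_meta.loc[obs],
                           self.gene_meta)

    def roles(self) -> pd.Series:
        if "role" not in self.obs_meta:
            return pd.Series(pd.NA, index=self.obs, dtype=object)
        return self.obs_meta["role"]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_counts(path: str | Path, format: str = "dense_delimited",
                obs_meta: pd.DataFrame | None = None,
                role: str | None = None,
                gene_meta: GeneAnnotation | None = None) -> CountMatrix:
    """Load a count matrix from disk.

    ``format="dense_delimited"``: TSV/CSV with genes as rows, a header row
    of observation ids, first column gene ids (tab or comma, sniffed).

    ``format="mtx_triplet"``: MatrixMarket file ``<stem>.mtx`` with sidecar
    id files ``<stem>.genes.txt`` and ``<stem>.obs.txt`` (one id per line,
    matching row/column order).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dense_delimited":
        sep = "\t"
        with open(path) as fh:
            header = fh.readline()
        if "\t" not in header and "," in header:
            sep = ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise ValidationError(f"failed to parse {path}: {exc}") from exc
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        values = df
    elif format == "mtx_triplet":
        stem = path.with_suffix("")
        genes_file = Path(str(stem) + ".genes.txt")
        obs_file = Path(str(stem) + ".obs.txt")
        for f in (genes_file, obs_file):
            if not f.exists():
                raise FileNotFoundError(
                    f"MTX input requires id sidecar file {f}")
        try:
            mat = spio.mmread(path)
        except Exception as exc:
            raise ValidationError(f"failed to parse {path}: {exc}") from exc
        genes = genes_file.read_text().split()
        obs = obs_file.read_text().split()
        mat = sparse.coo_matrix(mat)
        if mat.shape != (len(genes), len(obs)):
            raise ValidationError(
                f"{path}: matrix shape {mat.shape} does not match "
                f"{len(genes)} genes x {len(obs)} observations")
        values = pd.DataFrame(mat.toarray(), index=pd.Index(genes),
                              columns=pd.Index(obs))
    else:
        raise ParameterError(f"unknown format {format!r}")

    if role is not None and obs_meta is None:
        obs_meta = pd.DataFrame({"role": role}, index=values.columns)
    return CountMatrix(values, obs_meta, gene_meta)


def write_counts(m: CountMatrix, path: str | Path,
                 format: str = "dense_delimited") -> None:
    """Write a count matrix in a format :func:`load_counts` reads back."""
    path = Path(path)
    if format == "dense_delimited":
        m.values.to_csv(path, sep="\t")
    elif format == "mtx_triplet":
        stem = path.with_suffix("")
        spio.mmwrite(str(path), sparse.coo_matrix(m.values.to_numpy()))
        Path(str(stem) + ".genes.txt").write_text(
            "\n".join(m.genes) + "\n")
        Path(str(stem) + ".obs.txt").write_text(
            "\n".join(m.obs) + "\n")
    else:
        raise ParameterError(f"unknown format {format!r}")


def write_obs_meta(m: CountMatrix, path: str | Path) -> None:
    m.obs_meta.to_csv(path, sep="\t")


def read_obs_meta(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_genes(m: CountMatrix, ann: GeneAnnotation,
                 keep_protein_coding: bool = True,
                 drop_mito: bool = True,
                 drop_ribo: bool = True) -> CountMatrix:
    """Gene-level QC: keep protein-coding, drop mitochondrial/ribosomal."""
    tab = ann.for_genes(m.genes)
    keep = pd.Series(True, index=m.genes)
    if keep_protein_coding:
        keep &= tab["protein_coding"]
    if drop_mito:
        keep &= ~tab["is_mitochondrial"]
    if drop_ribo:
        keep &= ~tab["is_ribosomal"]
    if not keep.any():
        raise ValidationError("gene filter left an empty gene set")
    logger.info("filter_genes: %d/%d genes retained", int(keep.sum()),
                len(keep))
    return m.subset_genes(m.genes[keep])


def filter_bulk_samples(m: CountMatrix,
                        min_umi: int = DEFAULT_BULK_MIN_UMI) -> CountMatrix:
    """Keep bulk samples with total UMIs strictly greater than ``min_umi``."""
    if len(m.obs) == 0:
        raise ValidationError("empty matrix: no bulk samples")
    totals = m.totals()
    keep = totals > min_umi
    logger.info("filter_bulk_samples: retained %d, dropped %d (min_umi=%d)",
                int(keep.sum()), int((~keep).sum()), min_umi)
    if not keep.any():
        raise ValidationError(
            f"all {len(keep)} bulk samples fall at or below {min_umi} UMIs")
    return m.subset_obs(m.obs[keep])


def filter_cells(m: CountMatrix, ann: GeneAnnotation | None = None,
                 umi_min: int = DEFAULT_CELL_UMI_MIN,
                 umi_max: int = DEFAULT_CELL_UMI_MAX,
                 max_mito_fraction: float = DEFAULT_MAX_MITO_FRACTION,
                 ) -> CountMatrix:
    """Cell QC: ``umi_min <= total <= umi_max`` (inclusive both ends) and
    mitochondrial fraction strictly below ``max_mito_fraction``."""
    if umi_min > umi_max:
        raise ParameterError(f"umi_min {umi_min} > umi_max {umi_max}")
    ann = ann if ann is not None else m.gene_meta
    if ann is None:
        raise ParameterError("filter_cells needs a GeneAnnotation for "
                             "mitochondrial flags")
    totals = m.totals()
    mito = ann.for_genes(m.genes)["is_mitochondrial"].to_numpy()
    mito_counts = m.values.loc[m.genes[mito]].sum(axis=0)
    with np.errstate(invalid="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / totals, 0.0)
    keep = (totals >= umi_min) & (totals <= umi_max) & \
        (mito_frac < max_mito_fraction)
    logger.info("filter_cells: retained %d/%d cells", int(keep.sum()),
                len(keep))
    return m.subset_obs(m.obs[keep])


def filter_pixels(m: CountMatrix,
                  min_umi: int = DEFAULT_PIXEL_MIN_UMI) -> CountMatrix:
    """Keep pixels with totals strictly greater than ``min_umi``."""
    totals = m.totals()
    keep = totals > min_umi
    if not keep.any():
        logger.warning("filter_pixels: no pixels above %d UMIs", min_umi)
    logger.info("filter_pixels: retained %d/%d pixels (min_umi=%d)",
                int(keep.sum()), len(keep), min_umi)
    return m.subset_obs(m.obs[keep])


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizedMatrix:
    """Per-observation expression fractions over ``normalization_genes``.

    Columns flagged in ``flagged`` had zero total counts on the subset and
    hold NaN; callers decide whether to drop them.
    """

    values: pd.DataFrame
    normalization_genes: pd.Index
    flagged: pd.Index
    obs_meta: pd.DataFrame

    def __post_init__(self) -> None:
        ok = self.values.columns.difference(self.flagged)
        sums = self.values[ok].sum(axis=0).to_numpy()
        if len(ok) and not np.allclose(sums, 1.0, atol=1e-9):
            raise ValidationError("normalized columns do not sum to 1")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def obs(self) -> pd.Index:
        return self.values.columns

    def drop_flagged(self) -> "NormalizedMatrix":
        keep = self.values.columns.difference(self.flagged, sort=False)
        return NormalizedMatrix(self.values[keep], self.normalization_genes,
                                pd.Index([]), self.obs_meta.loc[keep])

    def renormalize(self, gene_subset: Sequence[str]) -> "NormalizedMatrix":
        """Restrict to ``gene_subset`` and rescale fractions to sum to 1.

        Valid because fractions are proportional to the underlying counts.
        """
        return _normalize_frame(self.values, gene_subset, self.obs_meta)


def _normalize_frame(frame: pd.DataFrame, gene_subset,
                     obs_meta: pd.DataFrame) -> NormalizedMatrix:
    if isinstance(gene_subset, str):
        if gene_subset != "all":
            raise ParameterError("gene_subset must be 'all' or a gene list")
        genes = frame.index
    else:
        genes = pd.Index(gene_subset)
        if len(genes) == 0:
            raise ParameterError("empty gene subset")
        missing = genes.difference(frame.index)
        if len(missing):
            raise ParameterError(
                f"gene subset contains unknown genes: {list(missing[:5])}")
    sub = frame.loc[genes].astype(float)
    totals = sub.sum(axis=0)
    flagged = totals.index[totals == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = sub / totals.replace(0, np.nan)
    if len(flagged):
        logger.warning("sum_normalize: %d observations with zero counts on "
                       "the subset are flagged", len(flagged))
    return NormalizedMatrix(vals, genes, flagged, obs_meta)


def sum_normalize(m: CountMatrix,
                  gene_subset: Sequence[str] | str = "all",
                  ) -> NormalizedMatrix:
    """Divide each observation's counts by its total over ``gene_subset``."""
    return _normalize_frame(m.values, gene_subset, m.obs_meta)
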