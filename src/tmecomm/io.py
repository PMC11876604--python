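"""Expression-dataset and ligand-receptor registry input/output.

The on-disk layout mirrors the common single-cell exchange format: a
MatrixMarket coordinate matrix (genes x cells), ``genes.tsv`` and
``barcodes.tsv`` index files, and a ``metadata.tsv`` table of per-cell
annotations (patient, sample, collection day, cell type, optional subtype,
treatment arm, tumor response label).  Expression is kept on the
counts-per-million (CPM) scale throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

METADATA_COLUMNS = [
    "barcode",
    "patient",
    "sample",
    "day",
    "cell_type",
    "subtype",
    "treatment",
    "response",
]

#: float format used by every TSV writer, so that repeated runs of the same
#: seeded analysis produce byte-identical artifacts.
FLOAT_FORMAT = "%.10g"


@dataclass(frozen=True)
class LRPair:
    """A single ligand -> receptor signaling pathway.

    Pairs are single-ligand / single-receptor; multimeric receptor
    complexes are out of scope.  ``pathway_id`` is the pathway index ``k``
    used throughout the communication model.
    """

    ligand: str
    receptor: str
    pathway_id: str
    family: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor gene symbols must be non-empty")


class LRDatabase:
    """Validated, order-preserving registry of ligand-receptor pairs."""

    def __init__(self, pairs: Iterable[LRPair]):
        self.pairs: list[LRPair] = list(pairs)
        seen: dict[tuple[str, str], str] = {}
        dups = []
        for p in self.pairs:
            key = (p.ligand, p.receptor)
            if key in seen:
                dups.append(key)
            seen[key] = p.pathway_id
        if dups:
            raise ValueError(
                "duplicate (ligand, receptor) pairs in LR table: "
                + ", ".join(f"{l}->{r}" for l, r in dups)
            )
        ids = [p.pathway_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("pathway_id values must be unique")
        self._by_id = {p.pathway_id: p for p in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[LRPair]:
        return iter(self.pairs)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._by_id

    def __getitem__(self, pathway_id: str) -> LRPair:
        return self._by_id[pathway_id]

    @property
    def pathway_ids(self) -> list[str]:
        return [p.pathway_id for p in self.pairs]

    @property
    def genes(self) -> set[str]:
        """All ligand and receptor gene symbols appearing in the registry."""
        out: set[str] = set()
        for p in self.pairs:
            out.add(p.ligand)
            out.add(p.receptor)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand": [p.ligand for p in self.pairs],
                "receptor": [p.receptor for p in self.pairs],
                "pathway_id": [p.pathway_id for p in self.pairs],
                "family": ["|".join(sorted(p.family)) for p in self.pairs],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_lr_table(path: str | Path) -> LRDatabase:
    """Read a ligand-receptor pathway table from TSV.

    Required columns: ``ligand``, ``receptor``, ``pathway_id``; an optional
    ``family`` column may carry ``|``-separated annotation tags (cytokine,
    integrin, ...).  Gene symbols are whitespace-stripped and matched
    case-sensitively.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("ligand", "receptor", "pathway_id"):
        if col not in df.columns:
            raise ValueError(f"LR table is missing required column {col!r}")
    pairs = []
    for _, row in df.iterrows():
        fam = frozenset()
        if "family" in df.columns and isinstance(row.get("family"), str) and row["family"]:
            fam = frozenset(t.strip() for t in row["family"].split("|") if t.strip())
        pairs.append(
            LRPair(
                ligand=str(row["ligand"]).strip(),
                receptor=str(row["receptor"]).strip(),
                pathway_id=str(row["pathway_id"]).strip(),
                family=fam,
            )
        )
    return LRDatabase(pairs)


def filter_lr_to_universe(db: LRDatabase, genes: Iterable[str]) -> LRDatabase:
    """Retain pairs whose ligand AND receptor both occur in ``genes``."""
    universe = set(genes)
    kept = [p for p in db if p.ligand in universe and p.receptor in universe]
    dropped = len(db) - len(kept)
    if dropped:
        logger.info("filter_lr_to_universe: dropped %d of %d pairs", dropped, len(db))
    return LRDatabase(kept)


def cpm_normalize(counts, barcodes: Sequence[str] | None = None):
    """Scale each cell (row) of a cells x genes matrix to sum to one million.

    Accepts a dense array, a scipy sparse matrix, or a DataFrame (returned
    as the same type).  Cells with zero total counts cannot be normalized
    and raise an error listing the offending barcodes.
    """
    if isinstance(counts, pd.DataFrame):
        out = cpm_normalize(counts.to_numpy(dtype=float), barcodes=list(counts.index))
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    if sp.issparse(counts):
        mat = counts.tocsr().astype(float)
        totals = np.asarray(mat.sum(axis=1)).ravel()
        _check_totals(totals, barcodes)
        scale = sp.diags(1e6 / totals)
        return scale @ mat
    mat = np.asarray(counts, dtype=float)
    if np.any(mat < 0) or not np.all(np.isfinite(mat)):
        raise ValueError("counts must be finite and non-negative")
    totals = mat.sum(axis=1)
    _check_totals(totals, barcodes)
    return mat * (1e6 / totals)[:, None]


def _check_totals(totals: np.ndarray, barcodes: Sequence[str] | None) -> None:
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        names = [str(barcodes[i]) if barcodes is not None else str(i) for i in bad]
        raise ValueError(f"cells with zero total counts cannot be CPM-normalized: {names}")


@dataclass
class ExpressionDataset:
    """Cells x genes expression on CPM scale with per-cell annotations.

    ``matrix`` rows align with ``obs`` rows (indexed by barcode) and columns
    with ``genes``.  ``obs`` must carry patient, sample, day, cell_type,
    treatment and response columns; ``subtype`` is optional and may be
    filled in later by the subpopulation partition.
    """

    matrix: np.ndarray
    obs: pd.DataFrame
    genes: pd.Index

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.genes = pd.Index(self.genes)
        if self.matrix.shape != (len(self.obs), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.obs)} cells x {len(self.genes)} genes"
            )
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if not np.all(np.isfinite(self.matrix)) or np.any(self.matrix < 0):
            raise ValueError("expression must be finite and non-negative")
        missing = [c for c in ("patient", "sample", "day", "cell_type", "treatment", "response") if c not in self.obs.columns]
        if missing:
            raise ValueError(f"metadata is missing required columns: {missing}")
        # every sample maps to exactly one patient/day/treatment/response
        key = self.obs.groupby("sample")[["patient", "day", "treatment", "response"]].nunique()
        bad = key[(key > 1).any(axis=1)].index.tolist()
        if bad:
            raise ValueError(f"samples with inconsistent patient/day/treatment/response: {bad}")
        days = set(self.obs["day"].unique()) - {0, 14, 180}
        if days:
            warnings.warn(f"metadata contains days outside the 0/14/180 design: {sorted(days)}")

    # -- convenience ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.obs["sample"]))

    def subset(self, mask) -> "ExpressionDataset":
        mask = np.asarray(mask)
        return ExpressionDataset(self.matrix[mask], self.obs.iloc[mask].copy(), self.genes)

    def expression_frame(self, genes: Sequence[str] | None = None) -> pd.DataFrame:
        cols = self.genes if genes is None else pd.Index(genes)
        idx = self.genes.get_indexer(cols)
        if (idx < 0).any():
            missing = [g for g, i in zip(cols, idx) if i < 0]
            raise KeyError(f"genes not in dataset: {missing}")
        return pd.DataFrame(self.matrix[:, idx], index=self.obs.index, columns=cols)

    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.matrix.copy(),
            obs=self.obs.copy(),
            var=pd.DataFrame(index=self.genes),
        )

    # -- disk round trip ------------------------------------------------
    def write_dir(self, path: str | Path) -> Path:
        """Write MTX (genes x cells) + genes.tsv + barcodes.tsv + metadata.tsv."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path / "matrix.mtx"), sp.csr_matrix(self.matrix.T))
        (path / "genes.tsv").write_text("\n".join(self.genes) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(self.obs.index.astype(str)) + "\n")
        meta = self.obs.copy()
        meta.insert(0, "barcode", meta.index.astype(str))
        if "subtype" not in meta.columns:
            meta["subtype"] = ""
        meta[METADATA_COLUMNS].to_csv(
            path / "metadata.tsv", sep="\t", index=False, lineterminator="\n",
            float_format=FLOAT_FORMAT,
        )
        return path

    @classmethod
    def read_dir(cls, path: str | Path) -> "ExpressionDataset":
        path = Path(path)
        mat = scipy.io.mmread(str(path / "matrix.mtx"))
        mat = np.asarray(sp.csr_matrix(mat).todense()).T  # cells x genes
        genes = pd.Index((path / "genes.tsv").read_text().splitlines())
        barcodes = (path / "barcodes.tsv").read_text().splitlines()
        meta = pd.read_csv(path / "metadata.tsv", sep="\t", dtype={"barcode": str})
        meta = meta.set_index("barcode")
        meta = meta.loc[barcodes]
        meta["subtype"] = meta["subtype"].fillna("")
        return cls(mat, meta, genes)
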