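"""Core I/O: OTU tables, taxonomy, metadata, and shared configuration.

The :class:`OtuTable` is the universal input of every downstream stage:
an integer count matrix with samples as rows and OTUs as columns.
Tables can be read from wide TSV (a ``#OTU ID`` header is tolerated) or
from a dense BIOM-JSON subset, and written back losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "TaxonomyMap",
    "SampleMetadata",
    "PipelineConfig",
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "collapse_to_genus",
    "relative_abundance",
]

UNASSIGNED_GENUS = "unassigned"

TAXONOMIC_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class OtuTable:
    """Integer count matrix of shape (n_samples, n_otus).

    Parameters
    ----------
    sample_ids : list of str
        Ordered sample identifiers (rows).
    otu_ids : list of str
        Ordered OTU identifiers (columns).
    counts : ndarray of int
        Non-negative counts, shape ``(len(sample_ids), len(otu_ids))``.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            s, o = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[s]!r}, "
                f"OTU {self.otu_ids[o]!r}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def depths(self) -> np.ndarray:
        """Per-sample sequencing depth (row sums)."""
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def select_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        idx = {o: j for j, o in enumerate(self.otu_ids)}
        cols = [idx[o] for o in otu_ids]
        return OtuTable(list(self.sample_ids), list(otu_ids), self.counts[:, cols])

    def select_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return OtuTable(list(sample_ids), list(self.otu_ids), self.counts[rows, :])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class TaxonomyMap:
    """OTU id -> lineage mapping down to genus/species.

    ``lineages`` maps each OTU id to a dict with any subset of the keys
    in :data:`TAXONOMIC_RANKS`; levels below genus may be missing.
    """

    lineages: dict[str, dict[str, str]]

    def genus_of(self, otu_id: str) -> str | None:
        lin = self.lineages.get(otu_id)
        if lin is None:
            return None
        g = lin.get("genus")
        if g is not None and str(g).strip() == "":
            raise ValueError(f"empty genus label for OTU {otu_id!r}")
        return g

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages


@dataclass
class SampleMetadata:
    """Per-sample clinical/demographic table.

    Expected columns: ``age`` (years, fractional allowed), ``group``,
    ``sex``, ``bmi``, ``district``, ``uccs`` (0/1) and zero or more
    ``comorbidity_*`` 0/1 flags. Indexed by sample id.
    """

    frame: pd.DataFrame
    allowed_groups: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id in metadata: {dup!r}")
        if "age" in df.columns and (pd.to_numeric(df["age"]) < 0).any():
            bad = df.index[pd.to_numeric(df["age"]) < 0][0]
            raise ValueError(f"negative age for sample {bad!r}")
        if self.allowed_groups is not None and "group" in df.columns:
            extra = set(df["group"]) - set(self.allowed_groups)
            if extra:
                raise ValueError(f"undeclared group labels: {sorted(extra)}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def aligned_to(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing[:5]}")
        return self.frame.loc[list(sample_ids)]


@dataclass
class PipelineConfig:
    """Whole-pipeline parameters, serializable to JSON or YAML."""

    seed: int = 0
    rarefaction_fraction: float = 0.9
    rarefaction_resamples: int = 100
    rare_otu_fraction: float = 1e-5
    n_trees_regression: int = 500
    n_trees_classification: int = 1000
    n_taxa_selected: int = 30
    taxa_selection_iters: int = 100
    image_side: int = 256
    corr_threshold: float = 0.75
    n_bootstrap: int = 5000
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.rarefaction_fraction <= 1:
            raise ValueError("rarefaction_fraction must be in (0, 1]")
        if self.rarefaction_resamples < 1:
            raise ValueError("rarefaction_resamples must be >= 1")
        if not 0 <= self.rare_otu_fraction < 1:
            raise ValueError("rare_otu_fraction must be in [0, 1)")
        if self.image_side < 1:
            raise ValueError("image_side must be positive")
        if not 0 <= self.corr_threshold <= 1:
            raise ValueError("corr_threshold must be in [0, 1]")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_otu_table(
    path: str | Path, format: str = "tsv", orientation: str = "samples_as_rows"
) -> OtuTable:
    """Read an OTU count table.

    Parameters
    ----------
    path : path
        Input file.
    format : {"tsv", "biom-json"}
        ``tsv`` is a wide tab-separated table with a header row; a
        leading ``#OTU ID`` header cell is tolerated.  ``biom-json`` is
        the dense BIOM-JSON subset.
    orientation : {"samples_as_rows", "otus_as_rows"}
        How to interpret TSV rows.  Output is always samples x OTUs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        if df.index.name and df.index.name.lstrip("#").strip().lower() in (
            "otu id",
            "otu_id",
            "otuid",
        ):
            # classic BIOM-style TSV puts OTUs on rows
            if orientation == "samples_as_rows":
                orientation = "otus_as_rows"
        for col in df.columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = df.index[vals.isna()][0]
                raise ValueError(
                    f"non-numeric count at row {row!r}, column {col!r} in {path}"
                )
            df[col] = vals
        if (df.to_numpy() < 0).any():
            arr = df.to_numpy()
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at row {df.index[i]!r}, column "
                f"{df.columns[j]!r} in {path}"
            )
        if orientation == "otus_as_rows":
            df = df.T
        return OtuTable(list(df.index), list(df.columns), df.to_numpy())
    if format == "biom-json":
        data = json.loads(path.read_text())
        if data.get("matrix_type") != "dense":
            raise ValueError("only dense BIOM-JSON is supported")
        otu_ids = [r["id"] for r in data["rows"]]
        sample_ids = [c["id"] for c in data["columns"]]
        mat = np.asarray(data["data"], dtype=float)
        if mat.shape != (len(otu_ids), len(sample_ids)):
            raise ValueError(
                f"BIOM data shape {mat.shape} inconsistent with "
                f"{len(otu_ids)} rows x {len(sample_ids)} columns"
            )
        return OtuTable(sample_ids, otu_ids, mat.T)
    raise ValueError(f"unknown format {format!r}")


def write_otu_table(
    table: OtuTable, path: str | Path, format: str = "tsv"
) -> None:
    """Write an OTU table; ``tsv`` round-trips with :func:`read_otu_table`."""
    path = Path(path)
    if format == "tsv":
        df = table.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
    elif format == "biom-json":
        data = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_otus, table.n_samples],
            "rows": [{"id": o, "metadata": None} for o in table.otu_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.counts.T.tolist(),
        }
        path.write_text(json.dumps(data) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a 2-column TSV: OTU id, semicolon-separated lineage.

    Lineage fields may carry Greengenes-style ``g__`` prefixes or be
    bare names ordered kingdom..species.
    """
    lineages: dict[str, dict[str, str]] = {}
    prefix_map = {r[0]: r for r in TAXONOMIC_RANKS}
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed taxonomy line {ln + 1}: {line!r}")
            otu_id, lineage = parts[0], parts[1]
            fields = [f.strip() for f in lineage.split(";")]
            lin: dict[str, str] = {}
            for pos, f in enumerate(fields):
                if not f:
                    continue
                if len(f) >= 3 and f[1:3] == "__" and f[0] in prefix_map:
                    name = f[3:]
                    if name:
                        lin[prefix_map[f[0]]] = name
                elif pos < len(TAXONOMIC_RANKS):
                    lin[TAXONOMIC_RANKS[pos]] = f
            lineages[otu_id] = lin
    return TaxonomyMap(lineages)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for otu_id, lin in tax.lineages.items():
            fields = [
                f"{rank[0]}__{lin[rank]}" if rank in lin else f"{rank[0]}__"
                for rank in TAXONOMIC_RANKS
            ]
            fh.write(f"{otu_id}\t{';'.join(fields)}\n")


def read_metadata(
    path: str | Path, allowed_groups: Sequence[str] | None = None
) -> SampleMetadata:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    return SampleMetadata(
        df, tuple(allowed_groups) if allowed_groups is not None else None
    )


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


def collapse_to_genus(table: OtuTable, tax: TaxonomyMap) -> OtuTable:
    """Sum OTU counts into genus-level columns.

    OTUs without a genus assignment are pooled into a single
    ``unassigned`` column so that per-sample totals are conserved
    exactly.
    """
    genera: dict[str, list[int]] = {}
    n_assigned = 0
    for j, otu in enumerate(table.otu_ids):
        g = tax.genus_of(otu) if otu in tax else None
        if g is None:
            g = UNASSIGNED_GENUS
        else:
            n_assigned += 1
        genera.setdefault(g, []).append(j)
    if n_assigned == 0:
        raise ValueError("taxonomy does not cover any OTU in the table")
    names = sorted(g for g in genera if g != UNASSIGNED_GENUS)
    if UNASSIGNED_GENUS in genera:
        names.append(UNASSIGNED_GENUS)
    out = np.zeros((table.n_samples, len(names)), dtype=np.int64)
    for k, g in enumerate(names):
        out[:, k] = table.counts[:, genera[g]].sum(axis=1)
    return OtuTable(list(table.sample_ids), names, out)


def relative_abundance(table: OtuTable | np.ndarray) -> np.ndarray:
    """Row-normalize counts to relative abundances summing to 1.

    Raises if any sample has zero depth.
    """
    if isinstance(table, OtuTable):
        counts = table.counts
        ids = table.sample_ids
    else:
        counts = np.asarray(table, dtype=float)
        ids = [str(i) for i in range(counts.shape[0])]
    depths = counts.sum(axis=1)
    if (depths <= 0).any():
        bad = [ids[i] for i in np.flatnonzero(depths <= 0)]
        raise ValueError(f"zero-depth samples: {bad}")
    return counts / depths[:, None]
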