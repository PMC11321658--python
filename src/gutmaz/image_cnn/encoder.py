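"""Encode OTU abundance profiles as multi-channel square images.

Channel semantics (all values 0-255):

1. OTU-level abundance, one pixel per retained OTU;
2. genus-level abundance (sum over member OTUs) broadcast over the
   genus pixel block;
3. genus correlation weight (max |Spearman rho| over retained partner
   edges) broadcast over the genus block.

Abundances ``a`` are log10-transformed to ``t in [-1, 1]`` with floor
``eps = 1e-6`` (``a = 0`` pinned to -1) and linearly mapped to 0-255.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from gutmaz.io_core import OtuTable, TaxonomyMap, relative_abundance

__all__ = [
    "GenusLayout",
    "MicrobiotaImage",
    "AgeBinScheme",
    "select_top_otus",
    "build_genus_layout",
    "encode_image",
    "encode_cohort",
    "build_age_bins",
    "DEFAULT_BIN_SPANS",
]

LOG_EPS = 1e-6


@dataclass
class GenusBlock:
    genus: str
    start: int
    length: int
    otu_ids: list[str]
    corr_weight: float


@dataclass
class GenusLayout:
    """Deterministic pixel-block assignment of genera (row-major)."""

    blocks: list[GenusBlock]
    corr_threshold: float
    side: int

    def __post_init__(self) -> None:
        total = sum(b.length for b in self.blocks)
        if total > self.side * self.side:
            raise ValueError(
                f"layout needs {total} pixels but image has {self.side ** 2}"
            )
        pos = 0
        for b in self.blocks:
            if b.start != pos:
                raise ValueError("genus blocks must be contiguous and disjoint")
            pos += b.length

    @property
    def otu_order(self) -> list[str]:
        return [o for b in self.blocks for o in b.otu_ids]

    @property
    def n_pixels_used(self) -> int:
        return sum(b.length for b in self.blocks)

    def hash(self) -> str:
        payload = json.dumps(
            {
                "side": self.side,
                "threshold": self.corr_threshold,
                "blocks": [
                    [b.genus, b.start, b.length, b.otu_ids, round(b.corr_weight, 12)]
                    for b in self.blocks
                ],
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "side": self.side,
                    "corr_threshold": self.corr_threshold,
                    "hash": self.hash(),
                    "blocks": [
                        {
                            "genus": b.genus,
                            "start": b.start,
                            "length": b.length,
                            "otu_ids": b.otu_ids,
                            "corr_weight": b.corr_weight,
                        }
                        for b in self.blocks
                    ],
                },
                indent=2,
            )
            + "\n"
        )


@dataclass
class MicrobiotaImage:
    """Three-channel integer image of one sample, shape (3, L, L)."""

    sample_id: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[0] != 3 or p.shape[1] != p.shape[2]:
            raise ValueError(f"expected (3, L, L) pixels, got {p.shape}")
        if p.min() < 0 or p.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        self.pixels = p.astype(np.uint8)

    @property
    def side(self) -> int:
        return self.pixels.shape[1]

    def to_text(self, path: str | Path) -> None:
        """Plain-text dump: three L x L integer matrices separated by blank lines."""
        with open(path, "w") as fh:
            fh.write(f"# sample {self.sample_id}, side {self.side}\n")
            for c in range(3):
                np.savetxt(fh, self.pixels[c], fmt="%d")
                fh.write("\n")

    def to_png(self, path: str | Path) -> None:
        from PIL import Image

        Image.fromarray(np.moveaxis(self.pixels, 0, -1), mode="RGB").save(path)


def select_top_otus(table: OtuTable, n: int = 65536) -> OtuTable:
    """Keep the ``n`` highest-grand-total OTUs (ties by OTU id)."""
    if table.n_otus == 0:
        raise ValueError("empty table")
    totals = table.counts.sum(axis=0)
    order = sorted(
        range(table.n_otus), key=lambda j: (-totals[j], table.otu_ids[j])
    )
    keep = sorted(order[:n])  # preserve original column order
    return table.select_otus([table.otu_ids[j] for j in keep])


def build_genus_layout(
    genus_table: OtuTable,
    otu_ids_by_genus: Mapping[str, Sequence[str]],
    corr_threshold: float = 0.75,
    side: int = 256,
) -> GenusLayout:
    """Order genera by abundance with correlated partners adjacent.

    Pairwise genus Spearman correlations are computed on relative
    abundances; edges with correlation > ``corr_threshold`` are
    retained.  Genera are visited in descending mean relative abundance;
    after a genus is placed, its retained partners that are not yet
    placed are placed immediately after it (descending abundance among
    partners, recursively).  Each genus receives a contiguous row-major
    pixel block sized to its retained OTU count.
    """
    if genus_table.n_otus < 1:
        raise ValueError("need at least 1 genus")
    genera = list(genus_table.otu_ids)
    rel = relative_abundance(genus_table)
    mean_ab = rel.mean(axis=0)

    n_g = len(genera)
    corr = np.zeros((n_g, n_g))
    if n_g > 1:
        constant = rel.std(axis=0) == 0
        if constant.any():
            import warnings

            warnings.warn(
                f"constant genera get no correlation edges: "
                f"{[genera[j] for j in np.flatnonzero(constant)][:5]}"
            )
        # Spearman = Pearson on ranks; constant columns get rho = 0
        ranks = np.apply_along_axis(stats.rankdata, 0, rel)
        with np.errstate(invalid="ignore"):
            rho = np.corrcoef(ranks, rowvar=False)
        corr = np.nan_to_num(np.atleast_2d(rho), nan=0.0)
        np.fill_diagonal(corr, 0.0)

    partners = {
        j: [kk for kk in np.flatnonzero(corr[j] > corr_threshold)]
        for j in range(n_g)
    }

    def sort_key(j: int) -> tuple[float, str]:
        return (-mean_ab[j], genera[j])

    placed: list[int] = []
    placed_set: set[int] = set()

    def place(j: int) -> None:
        if j in placed_set:
            return
        placed.append(j)
        placed_set.add(j)
        for p in sorted(partners[j], key=sort_key):
            place(p)

    for j in sorted(range(n_g), key=sort_key):
        place(j)

    blocks = []
    pos = 0
    for j in placed:
        g = genera[j]
        otus = [str(o) for o in otu_ids_by_genus.get(g, [])]
        weight = float(np.abs(corr[j][corr[j] > corr_threshold]).max(initial=0.0))
        blocks.append(GenusBlock(g, pos, len(otus), otus, weight))
        pos += len(otus)
    return GenusLayout(blocks, corr_threshold, side)


def _abundance_to_pixel(a: np.ndarray, eps: float = LOG_EPS) -> np.ndarray:
    """Map relative abundance in [0,1] to integer pixel 0-255.

    ``t = clamp(2 * (log10(a) - log10(eps)) / (0 - log10(eps)) - 1, -1, 1)``
    with ``a = 0`` pinned to ``t = -1``; pixel = round((t+1)/2 * 255).
    """
    a = np.asarray(a, dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise ValueError("abundances must lie in [0, 1]")
    log_eps = np.log10(eps)
    with np.errstate(divide="ignore"):
        la = np.where(a > 0, np.log10(np.maximum(a, np.finfo(float).tiny)), log_eps)
    t = np.clip(2.0 * (la - log_eps) / (0.0 - log_eps) - 1.0, -1.0, 1.0)
    t = np.where(a == 0, -1.0, t)
    return np.round((t + 1.0) / 2.0 * 255.0).astype(np.uint8)


def encode_image(
    sample_abundances: Sequence[float],
    layout: GenusLayout,
    side: int | None = None,
    sample_id: str = "sample",
) -> MicrobiotaImage:
    """Encode one sample's OTU relative abundances as a 3-channel image.

    ``sample_abundances`` must be aligned to ``layout.otu_order``.
    Unused pixels are 0; an OTU with zero abundance also maps to pixel 0
    in channel 1 (the transform floor).
    """
    side = side or layout.side
    a = np.asarray(sample_abundances, dtype=float)
    if len(a) != layout.n_pixels_used:
        raise ValueError(
            f"expected {layout.n_pixels_used} abundances aligned to the "
            f"layout, got {len(a)}"
        )
    n_px = side * side
    if layout.n_pixels_used > n_px:
        raise ValueError("layout does not fit the requested image side")
    chan = np.zeros((3, n_px), dtype=np.uint8)
    otu_px = _abundance_to_pixel(a)
    # zero-abundance OTUs must be pixel 0 in channel 1
    otu_px = np.where(a == 0, 0, otu_px)
    chan[0, : len(a)] = otu_px
    for b in layout.blocks:
        if b.length == 0:
            continue
        genus_ab = a[b.start : b.start + b.length].sum()
        chan[1, b.start : b.start + b.length] = _abundance_to_pixel(
            np.array([min(genus_ab, 1.0)])
        )[0]
        chan[2, b.start : b.start + b.length] = int(round(b.corr_weight * 255))
    return MicrobiotaImage(sample_id, chan.reshape(3, side, side))


def encode_cohort(
    table: OtuTable,
    tax: TaxonomyMap,
    corr_threshold: float = 0.75,
    side: int = 256,
) -> tuple[list[MicrobiotaImage], GenusLayout]:
    """End-to-end: top-OTU selection, genus layout, per-sample images."""
    from gutmaz.io_core import collapse_to_genus

    top = select_top_otus(table, side * side)
    genus_table = collapse_to_genus(top, tax)
    by_genus: dict[str, list[str]] = {}
    for o in top.otu_ids:
        g = tax.genus_of(o) if o in tax else None
        by_genus.setdefault(g if g is not None else "unassigned", []).append(o)
    layout = build_genus_layout(genus_table, by_genus, corr_threshold, side)
    rel = relative_abundance(top)
    order_idx = [top.otu_ids.index(o) for o in layout.otu_order]
    images = [
        encode_image(rel[i, order_idx], layout, side, sample_id=sid)
        for i, sid in enumerate(top.sample_ids)
    ]
    return images, layout


# ---------------------------------------------------------------------------
# Physiological-age bins
# ---------------------------------------------------------------------------

# (span start, span end, bin width), all in years
DEFAULT_BIN_SPANS: tuple[tuple[float, float, float], ...] = (
    (0.0, 1.0, 1.0 / 12.0),
    (1.0, 2.0, 2.0 / 12.0),
    (2.0, 4.0, 3.0 / 12.0),
    (4.0, 10.0, 1.0),
    (10.0, 22.0, 2.0),
    (22.0, 40.0, 3.0),
    (40.0, 70.0, 5.0),
    (70.0, 102.0, 8.0),
)


@dataclass
class AgeBinScheme:
    """Ordered left-closed right-open age intervals used as CNN classes."""

    edges: np.ndarray  # length n_bins + 1
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=float)
        if len(e) < 2 or (np.diff(e) <= 0).any():
            raise ValueError("bin edges must be strictly increasing")
        self.edges = e
        if not self.labels:
            self.labels = [
                f"[{e[i]:g},{e[i + 1]:g})" for i in range(len(e) - 1)
            ]

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    @property
    def midpoints(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2.0

    def assign(self, ages: Sequence[float]) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        lo, hi = self.edges[0], self.edges[-1]
        bad = (ages < lo) | (ages > hi)
        if bad.any():
            raise ValueError(
                f"ages outside [{lo}, {hi}]: {ages[bad][:5].tolist()}"
            )
        idx = np.searchsorted(self.edges, ages, side="right") - 1
        return np.clip(idx, 0, self.n_bins - 1)  # age == hi joins the last bin


def _enumerate_default_edges(
    spans: Sequence[tuple[float, float, float]] = DEFAULT_BIN_SPANS,
) -> np.ndarray:
    edges = [spans[0][0]]
    for lo, hi, width in spans:
        e = lo
        while e < hi - 1e-9:
            e = min(e + width, hi)
            edges.append(round(e, 9))
    return np.asarray(edges)


def build_age_bins(
    scheme: str | Sequence[float] = "default",
    ages: Sequence[float] | None = None,
    min_count: int = 100,
) -> AgeBinScheme:
    """Construct the age-bin scheme, merging underfilled bins.

    ``scheme="default"`` enumerates the standard spans (0-1 monthly, 1-2
    every two months, 2-4 every three months, 4-10 yearly, 10-22 every
    two years, 22-40 every three years, 40-70 every five years, 70-102
    every eight years).  When training ``ages`` are supplied, adjacent
    bins are merged (each underfilled bin into its smaller neighbour)
    until every bin holds at least ``min_count`` samples.
    """
    if isinstance(scheme, str):
        if scheme != "default":
            raise ValueError(f"unknown scheme {scheme!r}")
        edges = _enumerate_default_edges()
    else:
        edges = np.asarray(scheme, dtype=float)
    bins = AgeBinScheme(edges)
    if ages is None:
        return bins
    ages = np.asarray(ages, dtype=float)
    counts = np.bincount(bins.assign(ages), minlength=bins.n_bins).tolist()
    edge_list = list(bins.edges)
    while len(counts) > 1 and min(counts) < min_count:
        i = int(np.argmin(counts))
        if i == 0:
            j = 1
        elif i == len(counts) - 1:
            j = i - 1
        else:
            j = i - 1 if counts[i - 1] <= counts[i + 1] else i + 1
        lo, hi = min(i, j), max(i, j)
        counts[lo] += counts[hi]
        del counts[hi]
        del edge_list[hi]  # remove shared interior edge
    if min(counts) < min_count:
        raise ValueError(
            f"cannot reach min_count={min_count} even with a single bin "
            f"({int(sum(counts))} samples)"
        )
    return AgeBinScheme(np.asarray(edge_list))
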