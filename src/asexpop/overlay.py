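"""Infinite-sites mutation overlay on a genealogy.

Mutations are placed on branches with probability proportional to a branch
duration: either the branch's total length ("total" mode) or only the
generations the branch spent in the asexual state ("pruned" mode).  Each
mutation creates a fresh biallelic column whose derived allele is carried by
exactly the tips descending from the mutated branch, so every output matrix
is a perfect phylogeny.

Branches whose descendant set is the full sample are excluded from
placement: a mutation there would be fixed in the sample rather than
segregating.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .genealogy import Genealogy, GenealogyError

__all__ = ["HaplotypeMatrix", "OverlayError", "overlay_fixed_S", "overlay_rate"]


class OverlayError(ValueError):
    """Overlay is infeasible (e.g. no branch carries weight)."""


@dataclass
class HaplotypeMatrix:
    """n samples x S biallelic sites; 0 = ancestral, 1 = derived."""

    samples: list[str]
    data: np.ndarray  # shape (n, S), dtype uint8
    locus_length: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.data.shape[0] != len(self.samples):
            raise ValueError("row count does not match sample count")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def S(self) -> int:
        return self.data.shape[1]

    def derived_counts(self) -> np.ndarray:
        return self.data.sum(axis=0).astype(np.int64)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("sample\t" + "\t".join(f"s{i}" for i in range(self.S)) + "\n")
        for name, row in zip(self.samples, self.data):
            buf.write(name + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_tsv(cls, text: str) -> "HaplotypeMatrix":
        lines = [ln for ln in text.strip().splitlines() if ln]
        samples, rows = [], []
        for ln in lines[1:]:
            parts = ln.split("\t")
            samples.append(parts[0])
            rows.append([int(v) for v in parts[1:]])
        return cls(samples, np.array(rows, dtype=np.uint8).reshape(len(samples), -1))

    def to_fasta01(self) -> str:
        """Debug view: one record per sample, characters '0'/'1'."""
        buf = io.StringIO()
        for name, row in zip(self.samples, self.data):
            buf.write(f">{name}\n" + "".join(str(int(v)) for v in row) + "\n")
        return buf.getvalue()


def _branch_weights(
    g: Genealogy, mode: str
) -> tuple[list[str], np.ndarray, dict[str, frozenset[str]]]:
    if mode not in ("total", "pruned"):
        raise ValueError(f"unknown overlay mode {mode!r}")
    g.validate()
    desc = g.descendant_tips()
    all_tips = desc[g.root]
    child_ids, weights = [], []
    for child, br in g.branches.items():
        if desc[child] == all_tips:
            continue  # mutation would be fixed in the sample
        w = br.total_gens if mode == "total" else br.asexual_gens
        child_ids.append(child)
        weights.append(w)
    return child_ids, np.asarray(weights, dtype=float), desc


def _columns_from_assignment(
    g: Genealogy,
    child_ids: list[str],
    counts: np.ndarray,
    desc: dict[str, frozenset[str]],
) -> HaplotypeMatrix:
    samples = list(g.samples)
    idx = {s: i for i, s in enumerate(samples)}
    S = int(counts.sum())
    data = np.zeros((len(samples), S), dtype=np.uint8)
    col = 0
    for child, c in zip(child_ids, counts):
        if c == 0:
            continue
        rows = [idx[t] for t in desc[child] if t in idx]
        for _ in range(int(c)):
            data[rows, col] = 1
            col += 1
    return HaplotypeMatrix(samples, data)


def overlay_fixed_S(
    g: Genealogy, S: int, mode: str, rng: np.random.Generator
) -> HaplotypeMatrix:
    """Place exactly ``S`` mutations, multinomially over branch durations."""
    if S < 0:
        raise ValueError("S must be non-negative")
    child_ids, weights, desc = _branch_weights(g, mode)
    if S == 0:
        return HaplotypeMatrix(list(g.samples), np.zeros((len(g.samples), 0)))
    tot = weights.sum()
    if tot <= 0:
        raise OverlayError(
            f"no branch carries weight in {mode!r} mode; cannot place {S} sites"
        )
    counts = rng.multinomial(S, weights / tot)
    return _columns_from_assignment(g, child_ids, counts, desc)


def overlay_rate(
    g: Genealogy, mu: float, mode: str, rng: np.random.Generator
) -> HaplotypeMatrix:
    """Poisson overlay: branch counts ~ Poisson(mu x selected duration)."""
    if mu < 0:
        raise ValueError("mutation rate must be non-negative")
    child_ids, weights, desc = _branch_weights(g, mode)
    counts = rng.poisson(mu * weights) if len(weights) else np.zeros(0, dtype=int)
    return _columns_from_assignment(g, child_ids, counts, desc)


def overlay_fixed_S_counts(
    g: Genealogy, S: int, mode: str, rng: np.random.Generator
) -> np.ndarray:
    """Fast path: derived-allele count per mutation, without the matrix.

    Equivalent in distribution to ``overlay_fixed_S(...).derived_counts()``
    restricted to sampled tips; used by the calibration loops where only the
    frequency spectrum matters.
    """
    child_ids, weights, desc = _branch_weights(g, mode)
    if S == 0:
        return np.zeros(0, dtype=np.int64)
    tot = weights.sum()
    if tot <= 0:
        raise OverlayError(f"no branch carries weight in {mode!r} mode")
    sample_set = set(g.samples)
    sizes = np.array(
        [len(desc[c] & sample_set) for c in child_ids], dtype=np.int64
    )
    counts = rng.multinomial(S, weights / tot)
    return np.repeat(sizes, counts)
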