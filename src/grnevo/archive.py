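"""Shared container for sampled genotypes tagged with fitness and metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Genotype

__all__ = ["GenotypeArchive"]


class GenotypeArchive:
    """Ordered collection of regulation matrices with fitness and tags.

    Used for both the multicanonical samples and the evolutionary-simulation
    archives.  Matrices are stored raw (int8) for compactness; ``genotype(i)``
    materialises a validated :class:`Genotype`.
    """

    def __init__(self, input_gene: int = 0, output_gene: int = 1,
                 seed: int | None = None):
        self.input_gene = input_gene
        self.output_gene = output_gene
        self.seed = seed
        self.matrices: list[np.ndarray] = []
        self.fitness: list[float] = []
        self.extra: dict[str, list] = {}

    def add(self, matrix: np.ndarray, fitness: float, **tags) -> None:
        self.matrices.append(np.asarray(matrix, dtype=np.int8))
        self.fitness.append(float(fitness))
        for k, v in tags.items():
            self.extra.setdefault(k, [None] * (len(self.matrices) - 1)).append(v)
        for k in self.extra:
            if k not in tags:
                self.extra[k].append(None)

    def __len__(self) -> int:
        return len(self.matrices)

    def genotype(self, i: int) -> Genotype:
        m = self.matrices[i]
        return Genotype(m.shape[0], m.copy(), self.input_gene, self.output_gene)

    def genotypes(self) -> list[Genotype]:
        return [self.genotype(i) for i in range(len(self))]

    @property
    def fitness_array(self) -> np.ndarray:
        return np.asarray(self.fitness, dtype=np.float64)

    def bin_indices(self, scheme) -> np.ndarray:
        from .multicanonical import fitness_bin
        return np.array([fitness_bin(f, scheme) for f in self.fitness],
                        dtype=np.int64)

    def select(self, mask) -> "GenotypeArchive":
        idx = np.nonzero(np.asarray(mask))[0]
        out = GenotypeArchive(self.input_gene, self.output_gene, self.seed)
        for i in idx:
            out.matrices.append(self.matrices[i])
            out.fitness.append(self.fitness[i])
        for k, vals in self.extra.items():
            out.extra[k] = [vals[i] for i in idx]
        return out

    def in_bin(self, k: int, scheme) -> "GenotypeArchive":
        return self.select(self.bin_indices(scheme) == k)

    def by_bin(self, scheme) -> dict[int, "GenotypeArchive"]:
        bins = self.bin_indices(scheme)
        return {int(k): self.select(bins == k) for k in np.unique(bins)}

    def extend(self, other: "GenotypeArchive") -> None:
        for i in range(len(other)):
            tags = {k: other.extra[k][i] for k in other.extra}
            self.add(other.matrices[i], other.fitness[i], **tags)

    def to_frame(self):
        import pandas as pd
        data = {"fitness": self.fitness_array}
        for k, vals in self.extra.items():
            data[k] = vals
        return pd.DataFrame(data)
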