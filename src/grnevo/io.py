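"""Serialization and ensemble comparison.

Genotype files come in two dialects (0-based indices everywhere):

* JSON: ``{"n_genes": N, "input_gene": 0, "output_gene": 1,
  "edges": [[source, target, sign], ...]}``
* TSV: three columns ``source  target  sign``, optionally preceded by
  comment headers ``# n_genes=N``, ``# input_gene=0``, ``# output_gene=1``
  (without them, N is inferred from the largest index and the terminals
  default to genes 0 and 1).

:func:`compare_ensembles` tabulates, per fitness bin and per method, the
phenotype fractions (summing to one) and essential-edge statistics, each
with three-times-standard-error error bars.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .archive import GenotypeArchive
from .model import Genotype, ModelParams
from .multicanonical import BinScheme
from .phenotype import MONOSTABLE, ONE_WAY, TOGGLE, classify
from .robustness import essential_edges

__all__ = [
    "GenotypeFormatError", "read_genotype", "write_genotype",
    "annotate_archive", "compare_ensembles",
    "RunManifest", "save_archive", "load_archive",
]

PHENOTYPE_LABELS = (MONOSTABLE, TOGGLE, ONE_WAY)


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype files, with a specific diagnostic."""


def _genotype_from_edges(n_genes, input_gene, output_gene, edges, where):
    try:
        n_genes = int(n_genes)
        input_gene = int(input_gene)
        output_gene = int(output_gene)
    except (TypeError, ValueError) as exc:
        raise GenotypeFormatError(f"{where}: non-integer header field: {exc}")
    mat = np.zeros((n_genes, n_genes), dtype=np.int8)
    seen = set()
    for k, edge in enumerate(edges):
        if len(edge) != 3:
            raise GenotypeFormatError(
                f"{where}: edge {k} has {len(edge)} fields, expected "
                f"(source, target, sign)")
        try:
            src, tgt, sign = (int(v) for v in edge)
        except (TypeError, ValueError):
            raise GenotypeFormatError(f"{where}: edge {k} has non-integer fields")
        if sign not in (-1, 1):
            raise GenotypeFormatError(
                f"{where}: edge {k} has sign {sign}, expected -1 or +1")
        if not (0 <= src < n_genes and 0 <= tgt < n_genes):
            raise GenotypeFormatError(
                f"{where}: edge {k} index ({src}, {tgt}) out of range for "
                f"{n_genes} genes")
        if (src, tgt) in seen:
            raise GenotypeFormatError(
                f"{where}: duplicate edge ({src}, {tgt})")
        seen.add((src, tgt))
        mat[tgt, src] = sign
    try:
        return Genotype(n_genes, mat, input_gene, output_gene)
    except ValueError as exc:
        raise GenotypeFormatError(f"{where}: {exc}")


def read_genotype(path: str | Path, fmt: str | None = None) -> Genotype:
    """Read a genotype from JSON or TSV (inferred from the suffix)."""
    path = Path(path)
    fmt = fmt or ("tsv" if path.suffix.lower() in (".tsv", ".txt") else "json")
    text = path.read_text()
    if fmt == "json":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise GenotypeFormatError(f"{path}: invalid JSON: {exc}")
        for key in ("n_genes", "edges"):
            if key not in doc:
                raise GenotypeFormatError(f"{path}: missing required key {key!r}")
        return _genotype_from_edges(
            doc["n_genes"], doc.get("input_gene", 0), doc.get("output_gene", 1),
            doc["edges"], str(path))
    if fmt == "tsv":
        headers = {}
        edges = []
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    headers[k.strip()] = v.strip()
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise GenotypeFormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            edges.append(fields)
        if not edges and "n_genes" not in headers:
            raise GenotypeFormatError(f"{path}: empty edge list and no n_genes header")
        n_genes = headers.get(
            "n_genes",
            1 + max(max(int(e[0]), int(e[1])) for e in edges) if edges else 2)
        n_genes = max(int(n_genes), 2)
        return _genotype_from_edges(
            n_genes, headers.get("input_gene", 0), headers.get("output_gene", 1),
            edges, str(path))
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotype(g: Genotype, path: str | Path, fmt: str | None = None) -> None:
    """Write a genotype as JSON or TSV (inferred from the suffix)."""
    path = Path(path)
    fmt = fmt or ("tsv" if path.suffix.lower() in (".tsv", ".txt") else "json")
    if fmt == "json":
        doc = {
            "n_genes": g.n_genes,
            "input_gene": g.input_gene,
            "output_gene": g.output_gene,
            "edges": [list(e) for e in g.edges()],
        }
        path.write_text(json.dumps(doc, indent=1) + "\n")
    elif fmt == "tsv":
        lines = [f"# n_genes={g.n_genes}",
                 f"# input_gene={g.input_gene}",
                 f"# output_gene={g.output_gene}",
                 "# source\ttarget\tsign"]
        lines += [f"{s}\t{t}\t{v}" for s, t, v in g.edges()]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# archives and ensemble comparison
# ---------------------------------------------------------------------------

def save_archive(archive: GenotypeArchive, path: str | Path) -> None:
    """Write an archive as one JSON document (genotypes as edge lists)."""
    doc = {
        "input_gene": archive.input_gene,
        "output_gene": archive.output_gene,
        "seed": archive.seed,
        "samples": [
            {
                "n_genes": int(m.shape[0]),
                "edges": [[int(s), int(t), int(m[t, s])]
                          for t, s in zip(*np.nonzero(m))],
                "fitness": archive.fitness[i],
                **{k: archive.extra[k][i] for k in archive.extra},
            }
            for i, m in enumerate(archive.matrices)
        ],
    }
    Path(path).write_text(json.dumps(doc) + "\n")


def load_archive(path: str | Path) -> GenotypeArchive:
    doc = json.loads(Path(path).read_text())
    archive = GenotypeArchive(doc["input_gene"], doc["output_gene"],
                              doc.get("seed"))
    for rec in doc["samples"]:
        n = rec["n_genes"]
        mat = np.zeros((n, n), dtype=np.int8)
        for src, tgt, sign in rec["edges"]:
            mat[tgt, src] = sign
        tags = {k: v for k, v in rec.items()
                if k not in ("n_genes", "edges", "fitness")}
        archive.add(mat, rec["fitness"], **tags)
    return archive


def annotate_archive(archive: GenotypeArchive,
                     params: ModelParams = ModelParams(),
                     scheme: BinScheme = BinScheme(),
                     with_essential: bool = True) -> pd.DataFrame:
    """Phenotype-classify (and optionally edge-cut-profile) every sample.

    Returns a DataFrame with columns fitness, bin, phenotype, n_essential
    plus any archive tags.
    """
    phenos = []
    n_ess = []
    for i in range(len(archive)):
        g = archive.genotype(i)
        phenos.append(classify(g, params).label)
        n_ess.append(essential_edges(g, params).n_essential
                     if with_essential else np.nan)
    df = archive.to_frame()
    df["bin"] = archive.bin_indices(scheme)
    df["phenotype"] = phenos
    df["n_essential"] = n_ess
    return df


def _summarise(df: pd.DataFrame, method: str) -> pd.DataFrame:
    rows = []
    for b, grp in df.groupby("bin"):
        n = len(grp)
        row = {"method": method, "bin": int(b), "n": n}
        for label in PHENOTYPE_LABELS:
            frac = (grp["phenotype"] == label).mean()
            row[f"frac_{label}"] = frac
            # binomial standard error; the paper-style error bar is 3 SE
            row[f"frac_{label}_3se"] = 3 * np.sqrt(frac * (1 - frac) / n)
        ne = grp["n_essential"].to_numpy(dtype=float)
        row["mean_n_essential"] = np.nanmean(ne)
        row["mean_n_essential_3se"] = (
            3 * np.nanstd(ne, ddof=1) / np.sqrt(n) if n > 1 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def compare_ensembles(df_a: pd.DataFrame, df_b: pd.DataFrame,
                      bins: int | list[int] | None = None,
                      labels: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Per-bin comparison table of two annotated ensembles.

    Inputs are DataFrames from :func:`annotate_archive`.  Restricting to a
    bin (or list of bins) with no members in either ensemble is an error.
    """
    if bins is not None:
        bins = [bins] if np.isscalar(bins) else list(bins)
        for b in bins:
            if not ((df_a["bin"] == b).any() or (df_b["bin"] == b).any()):
                raise ValueError(f"bin {b} is empty in both ensembles")
        df_a = df_a[df_a["bin"].isin(bins)]
        df_b = df_b[df_b["bin"].isin(bins)]
    out = pd.concat([_summarise(df_a, labels[0]), _summarise(df_b, labels[1])],
                    ignore_index=True)
    return out.sort_values(["bin", "method"]).reset_index(drop=True)


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    config: dict
    seed: int | None
    outputs: list[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__
            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(
                datetime.timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, default=str) + "\n")
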