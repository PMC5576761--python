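"""Readers, writers, run configuration and seed management.

All on-disk formats are TSV: matrices have a header row of study ids and a
first column of gene ids; results have one row per gene with one fdr column
(and one selection column) per requested k.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from .independent import FdrResult
from .models import MatrixError, Scale, StudyMatrix

__all__ = [
    "RunConfig",
    "load_config",
    "child_rng",
    "read_matrix",
    "write_matrix",
    "read_truth",
    "write_truth",
    "write_results",
    "read_results",
    "write_partition",
]


@dataclass
class RunConfig:
    """Settings shared by the pipeline subcommands; flags override file values."""

    mode: str = "screen"
    k: list = field(default_factory=lambda: [2])
    fdr_threshold: float = 0.2
    n_configs: int = 1024
    edge_threshold: float = 0.1
    bootstrap: int = 100
    estimator: str = "normix"
    null: str = "theoretical"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.fdr_threshold <= 1.0:
            raise ValueError("fdr threshold must be in (0, 1]")
        if not 0.0 < self.edge_threshold <= 1.0:
            raise ValueError("edge threshold must be in (0, 1]")
        if any(int(k) < 1 for k in self.k):
            raise ValueError("k values must be >= 1")
        self.k = [int(v) for v in self.k]


def load_config(path: str | None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML key/value file plus flag
    overrides (flags win; None overrides are ignored)."""
    values = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        values.update(data)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def child_rng(master_seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG fanned out from one master seed."""
    tag = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))


def parse_k_spec(spec: str) -> list:
    """Parse a k list like '2:5' (inclusive range) or '2,3,7'."""
    spec = spec.strip()
    if ":" in spec:
        lo, hi = spec.split(":")
        return list(range(int(lo), int(hi) + 1))
    return [int(v) for v in spec.split(",") if v]


# ---------------------------------------------------------------------------
# matrices


def read_matrix(path: str, scale: str | Scale) -> StudyMatrix:
    """Read a gene x study TSV matrix, validating shape and cell contents.

    Errors name the offending line number (ragged rows, non-numeric cells)
    or the duplicated gene id.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise MatrixError(f"{path}: empty file")
        cols = header.split("\t")
        study_ids = cols[1:] if len(cols) > 1 else []
        if not study_ids:
            raise MatrixError(f"{path}: header has no study columns")
        m = len(study_ids)
        gene_ids = []
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != m + 1:
                raise MatrixError(
                    f"{path}:{lineno}: expected {m + 1} fields, got {len(parts)}"
                )
            gene_ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise MatrixError(f"{path}:{lineno}: non-numeric cell ({exc})") from exc
    if len(set(gene_ids)) != len(gene_ids):
        seen = set()
        dup = next(g for g in gene_ids if g in seen or seen.add(g))
        raise MatrixError(f"{path}: duplicate gene id {dup!r}")
    return StudyMatrix(np.asarray(rows, dtype=float), gene_ids, study_ids, Scale(scale))


def write_matrix(Z: StudyMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(Z.study_ids) + "\n")
        for gid, row in zip(Z.gene_ids, Z.values):
            fh.write(gid + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


def write_truth(H: np.ndarray, gene_ids, study_ids, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(study_ids) + "\n")
        for gid, row in zip(gene_ids, np.asarray(H, dtype=int)):
            fh.write(gid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_truth(path: str):
    """Read a binary truth matrix; returns (H, gene_ids, study_ids)."""
    Z = read_matrix(path, Scale.zscore)
    H = Z.values
    if not np.isin(H, (0.0, 1.0)).all():
        raise MatrixError(f"{path}: truth matrix must be binary")
    return H.astype(np.int8), Z.gene_ids, Z.study_ids


# ---------------------------------------------------------------------------
# results


def write_results(results: list[FdrResult], path: str) -> None:
    """One row per gene; per-k fdr columns (6 significant digits) followed
    by per-k selection flags, ks in increasing order."""
    results = sorted(results, key=lambda r: r.k)
    if results:
        gene_ids = results[0].gene_ids
        for r in results[1:]:
            if r.gene_ids != gene_ids:
                raise ValueError("results must share one gene universe")
    else:
        gene_ids = []
    header = (
        ["gene"]
        + [f"fdr_k{r.k}" for r in results]
        + [f"selected_k{r.k}" for r in results]
    )
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i, gid in enumerate(gene_ids):
            cells = [gid]
            cells += [format(r.fdr[i], ".6g") for r in results]
            cells += [str(int(r.selected[i])) for r in results]
            fh.write("\t".join(cells) + "\n")


def read_results(path: str, threshold: float = 0.2) -> list[FdrResult]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ks = [int(c[len("fdr_k") :]) for c in header if c.startswith("fdr_k")]
        gene_ids = []
        values = {k: [] for k in ks}
        selected = {k: [] for k in ks}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            gene_ids.append(parts[0])
            for pos, k in enumerate(ks):
                values[k].append(float(parts[1 + pos]))
                selected[k].append(bool(int(parts[1 + len(ks) + pos])))
    return [
        FdrResult(
            gene_ids,
            k,
            np.array(values[k]),
            threshold=threshold,
            selected=np.array(selected[k], dtype=bool),
        )
        for k in ks
    ]


def write_partition(partition, study_ids, path: str) -> None:
    """One line per cluster, member study ids tab-separated."""
    with open(path, "w") as fh:
        for members in partition.clusters:
            fh.write("\t".join(study_ids[j] for j in members) + "\n")
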