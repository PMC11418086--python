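"""Plain-text file formats for matrices, rotations and labels.

Matrix file: first line ``n``, then 2n whitespace-separated rows of n
floats.  Rotations file: CSV, one row per image: index followed by the
nine row-major entries of the rotation.  Labels file: CSV ``index,label``.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np

from .geometry import CommonLinesMatrix, validate_rotation
from .recovery import nearest_rotation

__all__ = [
    "RunConfig",
    "read_labels",
    "read_matrix",
    "read_rotations",
    "write_labels",
    "write_matrix",
    "write_rotations",
]


class FormatError(ValueError):
    pass


class RunConfig:
    """Run-wide configuration: seed, log level, and solver parameters.

    Round-trips losslessly through a JSON file; unknown sections are
    preserved.  Subcommand flags override config-file values.
    """

    def __init__(self, seed: int = 0, log_level: str = "warning", **groups):
        self.seed = int(seed)
        self.log_level = str(log_level)
        self.groups = groups  # e.g. {"admm": {...}, "cluster": {...}}

    def to_dict(self) -> dict:
        return {"seed": self.seed, "log_level": self.log_level, **self.groups}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        return cls(d.pop("seed", 0), d.pop("log_level", "warning"), **d)

    def save(self, path) -> None:
        import json

        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "RunConfig":
        import json

        return cls.from_dict(json.loads(Path(path).read_text()))

    def __eq__(self, other) -> bool:
        return isinstance(other, RunConfig) and self.to_dict() == other.to_dict()


def write_matrix(A: CommonLinesMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{A.n}\n")
        for row in A.data:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_matrix(path) -> CommonLinesMatrix:
    lines = Path(path).read_text().strip().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise FormatError(f"{path}:1: header must be the integer n") from exc
    if len(lines) - 1 != 2 * n:
        raise FormatError(
            f"{path}: expected {2 * n} data rows after the header, got {len(lines) - 1}"
        )
    rows = []
    for k, line in enumerate(lines[1:], start=2):
        vals = line.split()
        if len(vals) != n:
            raise FormatError(f"{path}:{k}: expected {n} values, got {len(vals)}")
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise FormatError(f"{path}:{k}: non-numeric entry") from exc
    data = np.array(rows)
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: non-finite entries")
    return CommonLinesMatrix(data)


def write_rotations(rots: list[np.ndarray], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for i, R in enumerate(rots):
            w.writerow([i] + [f"{v:.17g}" for v in np.asarray(R).reshape(-1)])


def read_rotations(path, tol: float = 1e-6) -> list[np.ndarray]:
    rots = []
    with open(path, newline="") as fh:
        for k, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            if len(row) != 10:
                raise FormatError(f"{path}:{k}: expected index + 9 entries")
            try:
                m = np.array([float(v) for v in row[1:]]).reshape(3, 3)
            except ValueError as exc:
                raise FormatError(f"{path}:{k}: non-numeric entry") from exc
            try:
                validate_rotation(m, tol=1e-12)
            except ValueError:
                proj = nearest_rotation(m)
                if np.max(np.abs(proj - m)) > tol or np.linalg.det(proj) < 0:
                    raise FormatError(
                        f"{path}:{k}: row is not a rotation within tolerance"
                    )
                warnings.warn(f"{path}:{k}: renormalized near-rotation row")
                m = proj
            rots.append(m)
    return rots


def write_labels(labels, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "community"])
        for i, lab in enumerate(labels):
            w.writerow([i, int(lab)])


def read_labels(path) -> np.ndarray:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if rows and rows[0] and not rows[0][1].lstrip("-").isdigit():
        rows = rows[1:]  # header
    pairs = [(int(r[0]), int(r[1])) for r in rows if r]
    labels = np.zeros(len(pairs), dtype=int)
    for i, lab in pairs:
        labels[i] = lab
    return labels
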