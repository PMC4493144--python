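"""Pairwise nucleotide distances: p-distance and Kimura 2-parameter.

Both models use *pairwise deletion*: a column is excluded from a pair's
comparison only when that pair carries a gap or ambiguity code there (not
complete deletion across the whole alignment).  Ambiguity codes are never
fractionally matched — any non-ACGT state simply removes the column for that
pair, and gaps and ``N`` are treated identically.

The K2P distance distinguishes transition (A<->G, C<->T) and transversion
proportions P and Q among compared sites:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

It is undefined (saturated) when either logarithm's argument is <= 0; callers
building trees may substitute a configured cap so one divergent outlier cannot
abort a whole matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .seqio import Alignment, encode_sequence

logger = logging.getLogger(__name__)

P_DISTANCE = "p-distance"
K2P = "K2P"
MODELS = (P_DISTANCE, K2P)


class UndefinedDistanceError(ValueError):
    """No comparable (both-unambiguous) sites between a pair of sequences."""


class SaturatedDistanceError(ValueError):
    """K2P log-domain violation: divergence beyond the model's range."""


@dataclass(frozen=True)
class SitePairCounts:
    """Per-pair site classification under pairwise deletion.

    ``n_compared`` counts columns where both sequences carry an unambiguous
    A/C/G/T; transitions are A<->G and C<->T mismatches, transversions all
    other mismatches.
    """

    n_compared: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if min(self.n_compared, self.n_transitions, self.n_transversions) < 0:
            raise ValueError("site-pair counts must be non-negative")
        if self.n_transitions + self.n_transversions > self.n_compared:
            raise ValueError("mismatches cannot exceed compared sites")

    @property
    def n_mismatches(self) -> int:
        return self.n_transitions + self.n_transversions


def _as_codes(seq: str | np.ndarray) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return encode_sequence(seq)


def classify_site_pairs(s1: str | np.ndarray, s2: str | np.ndarray) -> SitePairCounts:
    """Count compared / transition / transversion sites for one sequence pair."""
    a, b = _as_codes(s1), _as_codes(s2)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    both = (a < 4) & (b < 4)
    diff = both & (a != b)
    # codes: A=0 C=1 G=2 T=3 -> purines even, pyrimidines odd; a within-class
    # mismatch is a transition.
    ts = diff & ((a & 1) == (b & 1))
    return SitePairCounts(
        n_compared=int(both.sum()),
        n_transitions=int(ts.sum()),
        n_transversions=int(diff.sum() - ts.sum()),
    )


def p_distance(counts: SitePairCounts) -> float:
    """Proportion of differing sites among compared sites."""
    if counts.n_compared == 0:
        raise UndefinedDistanceError("no comparable sites: p-distance undefined")
    return counts.n_mismatches / counts.n_compared


def k2p_distance(counts: SitePairCounts) -> float:
    """Kimura 2-parameter corrected distance."""
    if counts.n_compared == 0:
        raise UndefinedDistanceError("no comparable sites: K2P distance undefined")
    P = counts.n_transitions / counts.n_compared
    Q = counts.n_transversions / counts.n_compared
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedDistanceError(
            f"K2P saturated (P={P:.4f}, Q={Q:.4f}): log argument <= 0"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix under a named model."""

    labels: tuple[str, ...]
    matrix: np.ndarray
    model: str

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError("matrix shape does not match number of labels")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.isfinite(m).all() and (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.matrix[i, j])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, model: str = P_DISTANCE) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                rows.append([float(x) for x in line.rstrip("\n").split("\t")[1:]])
        return cls(tuple(header), np.array(rows), model)

    def to_phylip(self, path: str | Path) -> None:
        """Square PHYLIP-style matrix (n on the first line)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.matrix):
                fh.write(f"{lab:<12s}" + " ".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path, model: str = P_DISTANCE) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().strip())
            labels, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(tuple(labels), np.array(rows), model)


def _pair_counts_vector(
    codes_i: np.ndarray, codes_rest: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compared / transition / transversion counts of one row vs many rows."""
    both = (codes_i < 4) & (codes_rest < 4)
    diff = both & (codes_rest != codes_i)
    ts = diff & ((codes_rest & 1) == (codes_i & 1))
    n_comp = both.sum(axis=1)
    n_ts = ts.sum(axis=1)
    n_tv = diff.sum(axis=1) - n_ts
    return n_comp, n_ts, n_tv


def build_distance_matrix(
    alignment: Alignment,
    model: str = P_DISTANCE,
    saturation_cap: float | None = None,
) -> DistanceMatrix:
    """All-pairs distance matrix under *model* with pairwise deletion.

    ``saturation_cap``: if given, K2P-saturated pairs are set to this value
    (substitutions/site) with a logged warning instead of raising; tree
    builders use a default cap of 5.0 so one divergent outlier cannot abort
    the build.  Pairs with zero comparable sites always raise, naming the pair.
    """
    if model not in MODELS:
        raise ValueError(f"unknown distance model {model!r}; expected one of {MODELS}")
    if len(alignment) < 2:
        raise ValueError("need at least 2 sequences for a distance matrix")
    codes = alignment.to_codes()
    n = len(alignment)
    D = np.zeros((n, n))
    labels = alignment.ids
    for i in range(n - 1):
        rest = codes[i + 1 :]
        n_comp, n_ts, n_tv = _pair_counts_vector(codes[i], rest)
        undefined = n_comp == 0
        if undefined.any():
            j = i + 1 + int(np.argmax(undefined))
            raise UndefinedDistanceError(
                f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
            )
        if model == P_DISTANCE:
            d = (n_ts + n_tv) / n_comp
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                P = n_ts / n_comp
                Q = n_tv / n_comp
                w1 = 1.0 - 2.0 * P - Q
                w2 = 1.0 - 2.0 * Q
                d = np.where(
                    (w1 > 0) & (w2 > 0),
                    -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
                    - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
                    np.inf,
                )
            saturated = ~np.isfinite(d)
            if saturated.any():
                j = i + 1 + int(np.argmax(saturated))
                if saturation_cap is None:
                    raise SaturatedDistanceError(
                        f"K2P saturated for pair ({labels[i]!r}, {labels[j]!r})"
                    )
                logger.warning(
                    "K2P saturated for %d pair(s) involving %r; capped at %g subs/site",
                    int(saturated.sum()),
                    labels[i],
                    saturation_cap,
                )
                d = np.where(saturated, saturation_cap, d)
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return DistanceMatrix(tuple(labels), D, model)


def distances_to_references(
    query: str | np.ndarray, references: Alignment
) -> np.ndarray:
    """p-distance of one query against every reference (pairwise deletion).

    Pairs with no comparable sites get ``nan``.
    """
    q = _as_codes(query)
    if q.shape[0] != references.length:
        raise ValueError("query length does not match reference frame")
    n_comp, n_ts, n_tv = _pair_counts_vector(q, references.to_codes())
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n_comp > 0, (n_ts + n_tv) / np.maximum(n_comp, 1), np.nan)
    return d
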