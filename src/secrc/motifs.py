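"""JASPAR position-frequency matrices and log-odds motif scanning.

A motif is a 4xL count matrix (rows A, C, G, T). Scanning converts counts
to pseudocounted frequencies, takes log2 odds against a background base
composition, and scores every position of a sequence on both strands. A
hit is any position whose score reaches ``score_fraction`` of the maximum
attainable score of the matrix — the convention used by core-regulatory-
circuitry mappers for deciding whether a TF's motif occurs in an enhancer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ParseError

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
# complement row permutation for A,C,G,T
_COMPLEMENT_ROWS = np.array([3, 2, 1, 0])
_NEG_INF = -1e9


@dataclass
class MotifMatrix:
    """A position frequency matrix with scanning parameters."""

    motif_id: str
    tf_name: str
    counts: np.ndarray  # 4 x L, rows A,C,G,T
    pseudocount: float = 1.0
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError(
                f"motif {self.motif_id}: counts must be 4 x L with L >= 4, "
                f"got {self.counts.shape}"
            )
        if np.any(self.counts < 0):
            raise ValueError(f"motif {self.motif_id}: negative counts")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise ValueError(f"motif {self.motif_id}: empty matrix column")
        if abs(float(self.background.sum()) - 1.0) > 1e-9:
            raise ValueError(
                f"motif {self.motif_id}: background must sum to 1"
            )

    @property
    def length(self) -> int:
        return int(self.counts.shape[1])

    def log_odds(self) -> np.ndarray:
        """4 x L log2-odds matrix from pseudocounted frequencies."""
        pseudo = self.pseudocount * self.background[:, None]
        freqs = (self.counts + pseudo) / (self.counts.sum(axis=0) + self.pseudocount)
        return np.log2(freqs / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.counts.argmax(axis=0))


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: 0-based start on the forward sequence."""

    position: int
    strand: str
    score: float


def _encode(sequence: str) -> np.ndarray:
    """Map ACGT to 0..3 and anything else (N...) to 4."""
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _scores_one_strand(encoded: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every window start for one 4xL log-odds matrix."""
    L = lo.shape[1]
    n = encoded.size - L + 1
    if n <= 0:
        return np.empty(0)
    # 5th row catches ambiguous bases: such windows can never reach threshold
    lo5 = np.vstack([lo, np.full(L, _NEG_INF)])
    scores = np.zeros(n)
    for j in range(L):
        scores += lo5[encoded[j:j + n], j]
    return scores


def pwm_scan(sequence: str, motif: MotifMatrix,
             score_fraction: float = 0.85) -> list[MotifHit]:
    """Scan both strands; return hits scoring >= fraction of the max.

    Positions are 0-based starts on the forward sequence regardless of
    strand. Sequences shorter than the motif yield no hits. Windows that
    contain an ambiguous base never reach the threshold.
    """
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    encoded = _encode(sequence)
    lo = motif.log_odds()
    threshold = score_fraction * motif.max_score()
    hits: list[MotifHit] = []
    fwd = _scores_one_strand(encoded, lo)
    # reverse complement of the matrix scans the minus strand in forward coords
    lo_rc = lo[_COMPLEMENT_ROWS][:, ::-1]
    rev = _scores_one_strand(encoded, lo_rc)
    for pos in np.flatnonzero(fwd >= threshold):
        hits.append(MotifHit(int(pos), "+", float(fwd[pos])))
    for pos in np.flatnonzero(rev >= threshold):
        hits.append(MotifHit(int(pos), "-", float(rev[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def read_jaspar(path: str | Path) -> list[MotifMatrix]:
    """Parse JASPAR (2016+) PFM text: ``>ID NAME`` then 4 bracketed rows.

    A header without a name field sets ``tf_name`` to the motif id. Row
    length mismatches and non-numeric counts raise :class:`ParseError`.
    """
    motifs: list[MotifMatrix] = []
    header: tuple[str, str] | None = None
    rows: list[list[float]] = []
    row_letters: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal header, rows, row_letters
        if header is None:
            return
        if len(rows) != 4:
            raise ParseError(
                f"{path}: motif {header[0]} has {len(rows)} count rows "
                "(need 4: A, C, G, T)"
            )
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ParseError(
                f"{path}: motif {header[0]}: count rows have unequal lengths "
                f"{sorted(len(r) for r in rows)}"
            )
        order = [row_letters.index(b) for b in "ACGT"] if set(row_letters) == set("ACGT") else [0, 1, 2, 3]
        counts = np.array([rows[i] for i in order])
        motifs.append(MotifMatrix(header[0], header[1], counts))
        header, rows, row_letters = None, [], []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                parts = line[1:].split(None, 1)
                if not parts:
                    raise ParseError(f"{path}: line {lineno}: empty motif header")
                motif_id = parts[0]
                tf_name = parts[1].strip() if len(parts) > 1 else motif_id
                header = (motif_id, tf_name)
                continue
            if header is None:
                raise ParseError(
                    f"{path}: line {lineno}: count row before any motif header"
                )
            letter = ""
            body = line
            if body and body[0].upper() in "ACGT" and (len(body) == 1 or not body[1].isdigit()):
                letter = body[0].upper()
                body = body[1:]
            body = body.replace("[", " ").replace("]", " ")
            try:
                values = [float(tok) for tok in body.split()]
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric count in motif "
                    f"{header[0]}"
                ) from None
            if any(v < 0 for v in values):
                raise ParseError(
                    f"{path}: line {lineno}: negative count in motif {header[0]}"
                )
            rows.append(values)
            row_letters.append(letter or "ACGT"[len(rows) - 1])
    flush(-1)
    return motifs


def write_jaspar(motifs: list[MotifMatrix], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.tf_name}\n")
            for letter, row in zip("ACGT", m.counts):
                cells = " ".join(f"{v:g}" for v in row)
                fh.write(f"{letter} [ {cells} ]\n")
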