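"""PWM scanning of regulatory sequences and per-group motif enrichment z-scores.

Scanning uses log-odds (base 2) against a background composition with a
small pseudocount; a window is a hit when its score reaches a configurable
fraction (default 0.8) of the maximum attainable score. Both strands are
scanned and hit coordinates are reported on the forward strand, 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PWM",
    "Hit",
    "read_jaspar",
    "write_jaspar",
    "read_meme",
    "scan_pwm",
    "motif_count_matrix",
    "motif_zscores",
]

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Position frequency matrix (rows A,C,G,T) with scanning parameters."""

    motif_id: str
    matrix: np.ndarray  # 4 x L column-normalized frequencies
    pseudocount: float = 1e-3
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold_fraction: float = 0.8

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A,C,G,T)")
        if self.length < 4:
            raise ValueError("PWM must be at least 4 columns long")
        colsums = self.matrix.sum(axis=0)
        if np.any(colsums <= 0):
            raise ValueError("PWM has an empty column")
        self.matrix = self.matrix / colsums
        self.background = np.asarray(self.background, dtype=float)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        freq = self.matrix + self.pseudocount
        freq = freq / freq.sum(axis=0)
        return np.log2(freq / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @classmethod
    def from_counts(cls, motif_id: str, counts: np.ndarray, **kw) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(motif_id=motif_id, matrix=counts / counts.sum(axis=0), **kw)


@dataclass
class Hit:
    sequence_id: str
    offset: int  # 0-based, forward strand
    strand: str  # "+" or "-"
    score: float


def read_jaspar(path) -> List[PWM]:
    """Minimal JASPAR reader: '>id name' header, then 4 lines 'A [ n n ... ]'."""
    pwms: List[PWM] = []
    motif_id = None
    rows: Dict[str, List[float]] = {}
    def flush():
        if motif_id is not None:
            counts = np.array([rows[b] for b in _ALPHABET])
            pwms.append(PWM.from_counts(motif_id, counts))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                motif_id = line[1:].split()[0]
                rows = {}
            else:
                base = line[0].upper()
                body = line[1:].replace("[", " ").replace("]", " ")
                rows[base] = [float(x) for x in body.split()]
    flush()
    return pwms


def write_jaspar(pwms: Iterable[PWM], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.motif_id}\n")
            counts = np.round(pwm.matrix * 100, 2)
            for i, base in enumerate(_ALPHABET):
                vals = " ".join(f"{v:g}" for v in counts[i])
                fh.write(f"{base} [ {vals} ]\n")


def read_meme(path) -> List[PWM]:
    """Minimal MEME text reader (MOTIF blocks with letter-probability matrices)."""
    pwms: List[PWM] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            j = i + 1
            while j < len(lines) and not lines[j].strip().startswith("letter-probability"):
                j += 1
            probs = []
            j += 1
            while j < len(lines):
                parts = lines[j].split()
                if len(parts) != 4:
                    break
                probs.append([float(x) for x in parts])
                j += 1
            pwms.append(PWM(motif_id=motif_id, matrix=np.array(probs).T))
            i = j
        else:
            i += 1
    return pwms


def _scan_one_strand(seq: str, lo: np.ndarray, L: int) -> np.ndarray:
    """Scores at each window start; NaN where the window contains N."""
    n = len(seq)
    if n < L:
        return np.empty(0)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for i, base in enumerate(_ALPHABET):
        lut[ord(base)] = i
    idx = lut[codes]
    scores = np.zeros(n - L + 1)
    valid = np.ones(n - L + 1, dtype=bool)
    for j in range(L):
        col_idx = idx[j : j + n - L + 1]
        ok = col_idx >= 0
        valid &= ok
        scores += np.where(ok, lo[np.clip(col_idx, 0, 3), j], 0.0)
    scores[~valid] = np.nan
    return scores


def scan_pwm(sequences: Mapping[str, str], pwm: PWM) -> List[Hit]:
    """All windows on both strands scoring >= threshold_fraction * max score.

    Windows containing N are skipped. Sequences shorter than the motif give
    no hits. Reverse-strand hit offsets refer to the forward strand.
    """
    lo = pwm.log_odds
    L = pwm.length
    threshold = pwm.threshold_fraction * pwm.max_score
    hits: List[Hit] = []
    for seq_id, seq in sequences.items():
        seq = seq.upper()
        fwd = _scan_one_strand(seq, lo, L)
        for off in np.flatnonzero(fwd >= threshold):
            hits.append(Hit(seq_id, int(off), "+", float(fwd[off])))
        rc = reverse_complement(seq)
        rev = _scan_one_strand(rc, lo, L)
        n = len(seq)
        for off in np.flatnonzero(rev >= threshold):
            hits.append(Hit(seq_id, int(n - L - off), "-", float(rev[off])))
    return hits


def motif_count_matrix(
    groups: Mapping[str, Sequence[Tuple[str, int, int]]],
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
) -> Tuple[pd.DataFrame, pd.Series]:
    """Hit counts per group per motif over region sets.

    ``groups`` maps a group id to regions (sequence_id, start, end) resolved
    against ``sequences``. Overlapping hits all count; a region listed twice
    is scanned twice (with a warning). Returns (counts, scanned bp per group).
    """
    counts = pd.DataFrame(
        0, index=list(groups), columns=[p.motif_id for p in pwms], dtype=int
    )
    scanned = pd.Series(0, index=list(groups), dtype=int)
    for gid, regions in groups.items():
        seen = set()
        region_seqs: Dict[str, str] = {}
        for i, (sid, start, end) in enumerate(regions):
            if sid not in sequences:
                raise ValueError(f"region references unknown sequence {sid!r}")
            seq = sequences[sid]
            if not (0 <= start < end <= len(seq)):
                raise ValueError(f"region {(sid, start, end)} outside sequence bounds")
            if (sid, start, end) in seen:
                warnings.warn(f"duplicated region {(sid, start, end)} in group {gid!r}", stacklevel=2)
            seen.add((sid, start, end))
            region_seqs[f"{gid}::{i}"] = seq[start:end]
            scanned[gid] += end - start
        for pwm in pwms:
            counts.at[gid, pwm.motif_id] += len(scan_pwm(region_seqs, pwm))
    return counts, scanned


def motif_zscores(counts: pd.DataFrame, scanned_bp: pd.Series) -> pd.DataFrame:
    """Per-motif z-scores of hits-per-kb rates across groups (sample sd, n-1).

    Motifs with zero rate variance across groups get a NaN column.
    """
    if counts.shape[0] < 2:
        raise ValueError("z-scores need at least 2 groups")
    kb = scanned_bp.reindex(counts.index).astype(float) / 1e3
    if (kb <= 0).any():
        raise ValueError("every group must have scanned bp > 0")
    rates = counts.div(kb, axis=0)
    mu = rates.mean(axis=0)
    sd = rates.std(axis=0, ddof=1)
    z = (rates - mu) / sd
    z.loc[:, sd == 0] = np.nan
    return z
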