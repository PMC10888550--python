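"""Plant miRNA target scoring by a gapless complementarity penalty.

A stand-in for dedicated plant-target predictors so the pipeline can derive
miRNA-target maps from sequences.  The duplex between a miRNA and a same-
length target-site window is scored position by position: +1 per mismatch,
+0.5 per G:U wobble, with penalties doubled inside the functional core
(positions 2-13 from the miRNA 5' end, where plant cleavage-guiding
complementarity matters most).  Perfect reverse-complement windows score 0.
Candidate sites are found by sliding over each transcript (gapless, no
bulges) and keeping the best window when its penalty is at or below a cutoff
(default 4.0, the conventional stringency for plant small-RNA target rules).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io import TargetPair

__all__ = ["DuplexScore", "score_duplex", "predict_targets", "read_fasta"]

_VALID = frozenset("ACGUT")

#: 1-based positions (from the miRNA 5' end) where penalties are doubled
CORE_START, CORE_END = 2, 13

_COMPLEMENT = {
    ("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class DuplexScore:
    mirna_id: str
    target_id: str
    position: int  # 0-based window start on the target (5'->3')
    penalty: float


def _normalize(seq: str, what: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - {"A", "C", "G", "U"}
    if bad:
        raise ValueError(f"invalid characters in {what}: {sorted(bad)}")
    return s


def _position_penalties(mirna: str, site: str) -> np.ndarray:
    """Per-miRNA-position penalties of the antiparallel gapless duplex.

    miRNA position i (5'->3') pairs with site position len-1-i.
    """
    if len(mirna) != len(site):
        raise ValueError("miRNA and target window must have equal length")
    pen = np.zeros(len(mirna))
    for i, m in enumerate(mirna):
        t = site[len(site) - 1 - i]
        if (m, t) in _COMPLEMENT:
            p = 0.0
        elif (m, t) in _WOBBLE:
            p = 0.5
        else:
            p = 1.0
        if CORE_START <= i + 1 <= CORE_END:
            p *= 2.0
        pen[i] = p
    return pen


def score_duplex(mirna_seq: str, target_site_seq: str,
                 mirna_id: str = "miRNA", target_id: str = "site") -> DuplexScore:
    """Penalty of the gapless duplex between a miRNA and an equal-length
    target-site window (both given 5'->3')."""
    m = _normalize(mirna_seq, "miRNA")
    s = _normalize(target_site_seq, "target site")
    penalty = float(_position_penalties(m, s).sum())
    return DuplexScore(mirna_id, target_id, 0, penalty)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


# penalty lookup: rows miRNA base, cols target base, order A C G U
_BASE_IDX = {ord("A"): 0, ord("C"): 1, ord("G"): 2, ord("U"): 3}
_PEN_TABLE = np.ones((4, 4))
for (m, t) in _COMPLEMENT:
    _PEN_TABLE["ACGU".index(m), "ACGU".index(t)] = 0.0
for (m, t) in _WOBBLE:
    _PEN_TABLE["ACGU".index(m), "ACGU".index(t)] = 0.5


def _best_window(mirna: str, transcript: str) -> tuple[float, int] | None:
    """(penalty, 0-based site start) of the best-scoring window, or None if
    the transcript is shorter than the miRNA."""
    L, n = len(mirna), len(transcript)
    if n < L:
        return None
    mi = np.array([_BASE_IDX[b] for b in _encode(mirna)])
    tx = np.array([_BASE_IDX[b] for b in _encode(transcript)])
    weights = np.ones(L)
    weights[CORE_START - 1: CORE_END] = 2.0
    # miRNA position i pairs with site position L-1-i => reverse the miRNA
    mi_rev = mi[::-1]
    w_rev = weights[::-1]
    windows = np.lib.stride_tricks.sliding_window_view(tx, L)
    pen = (_PEN_TABLE[mi_rev[None, :], windows] * w_rev[None, :]).sum(axis=1)
    best = int(np.argmin(pen))
    return float(pen[best]), best


def read_fasta(path) -> dict[str, str]:
    """id -> sequence map from a FASTA file."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def predict_targets(
    mirnas: Mapping[str, str] | str,
    transcripts: Mapping[str, str] | str,
    max_penalty: float = 4.0,
    target_class: str = "mRNA",
) -> list[TargetPair]:
    """Slide each miRNA over each transcript; emit pairs whose best gapless
    window penalty is <= max_penalty.

    ``mirnas`` and ``transcripts`` are id->sequence maps or FASTA paths.
    """
    if isinstance(mirnas, str):
        mirnas = read_fasta(mirnas)
    if isinstance(transcripts, str):
        transcripts = read_fasta(transcripts)
    if not mirnas or not transcripts:
        import warnings

        warnings.warn("empty sequence set: no targets predicted", stacklevel=2)
        return []
    pairs: list[TargetPair] = []
    for mid, mseq in mirnas.items():
        m = _normalize(mseq, f"miRNA {mid}")
        for tid, tseq in transcripts.items():
            if mid == tid:
                continue
            t = _normalize(tseq, f"transcript {tid}")
            hit = _best_window(m, t)
            if hit is None:
                continue
            penalty, _pos = hit
            if penalty <= max_penalty:
                pairs.append(TargetPair(mid, tid, target_class, penalty))
    return pairs
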