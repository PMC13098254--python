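"""Global pairwise protein alignment and reciprocal-best-hit ortholog mapping.

Identity between two proteins is defined on the optimal global alignment
(BLOSUM62 substitution scores, linear gap penalty) as
``matches / alignment columns * 100``.  Orthologs between a strain proteome
and the pan-genome are bidirectional best hits (BBH): each gene is the
other's highest-identity match and the identity clears the cutoff
(default 60%).
"""
from __future__ import annotations

from functools import lru_cache

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

GAP_SCORE = -8.0  # linear (open == extend) gap penalty per column
DEFAULT_CUTOFF = 60.0


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


def alignment_score(a: str, b: str) -> float:
    """Optimal global alignment score under BLOSUM62 with linear gaps."""
    return float(_aligner().score(a, b))


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity of the optimal global alignment of ``a`` and ``b``."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 100.0
    alignment = _aligner().align(a, b)[0]
    counts = alignment.counts()
    return 100.0 * counts.identities / alignment.length


def identity_upper_bound(len_a: int, len_b: int) -> float:
    """Length-based bound: matches <= min length, columns >= max length."""
    return 100.0 * min(len_a, len_b) / max(len_a, len_b)


def _best_hits(queries: dict[str, str], targets: dict[str, str], cutoff: float) -> dict[str, tuple[str, float]]:
    """Highest-identity target per query (ties to the lexicographically first id)."""
    hits: dict[str, tuple[str, float]] = {}
    for qid in sorted(queries):
        qseq = queries[qid]
        best_id, best_pct = None, -1.0
        for tid in sorted(targets):
            tseq = targets[tid]
            if identity_upper_bound(len(qseq), len(tseq)) < max(cutoff, best_pct):
                continue
            pct = pairwise_identity(qseq, tseq)
            if pct > best_pct:
                best_id, best_pct = tid, pct
        if best_id is not None and best_pct >= cutoff:
            hits[qid] = (best_id, best_pct)
    return hits


def bbh_map(
    strain_proteins: dict[str, str],
    pan_proteins: dict[str, str],
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Bidirectional best hits between a strain proteome and the pan proteome.

    Returns a table with columns ``strain_gene, pan_gene, identity_fwd,
    identity_rev``; each strain gene appears at most once.  The aligner is
    symmetric, so the two identities coincide; both columns are kept for the
    table contract.
    """
    if not strain_proteins or not pan_proteins:
        raise ValueError("both protein sets must be non-empty")
    fwd = _best_hits(strain_proteins, pan_proteins, cutoff)
    rev = _best_hits(pan_proteins, strain_proteins, cutoff)
    rows = []
    for sgene, (pgene, pct) in sorted(fwd.items()):
        back = rev.get(pgene)
        if back is not None and back[0] == sgene:
            rows.append({"strain_gene": sgene, "pan_gene": pgene, "identity_fwd": pct, "identity_rev": back[1]})
    return pd.DataFrame(rows, columns=["strain_gene", "pan_gene", "identity_fwd", "identity_rev"])
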