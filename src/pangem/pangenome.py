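"""Gene-family clustering, presence matrices, core-genome curves, strain blocks.

Families are built by greedy incremental clustering in the CD-HIT style:
records are sorted longest-first and each joins the first existing family
whose representative it matches at or above the identity threshold
(identity = matches / alignment columns on the optimal global alignment),
otherwise it founds a new family.  No k-mer prefiltering is used — at desk
scale the full alignment is exact and deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import pdist

from . import orthology

DEFAULT_IDENTITY = 0.90  # CD-HIT's default clustering threshold


@dataclass(frozen=True)
class ProteinRecord:
    strain: str
    gene: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for ({self.strain}, {self.gene})")


@dataclass
class GeneFamily:
    family_id: str
    representative: ProteinRecord
    members: list[ProteinRecord] = field(default_factory=list)
    identities: list[float] = field(default_factory=list)  # member identity to the representative, %

    @property
    def strains(self) -> set[str]:
        return {m.strain for m in self.members}


def cluster_gene_families(records: list[ProteinRecord], identity_threshold: float = DEFAULT_IDENTITY) -> list[GeneFamily]:
    """Greedy longest-first incremental clustering into gene families.

    Deterministic: ties in length are broken by (strain, gene) id, and each
    record joins the earliest-founded family that accepts it.
    """
    if not records:
        raise ValueError("no protein records to cluster")
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity threshold must be in (0, 1], got {identity_threshold}")
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.strain, r.gene))
    cutoff = identity_threshold * 100.0
    families: list[GeneFamily] = []
    by_exact: dict[str, int] = {}  # sequence -> family index fast path
    for rec in ordered:
        hit = by_exact.get(rec.sequence)
        if hit is not None:
            families[hit].members.append(rec)
            families[hit].identities.append(100.0)
            continue
        placed = False
        for idx, fam in enumerate(families):
            rep = fam.representative.sequence
            if orthology.identity_upper_bound(len(rec.sequence), len(rep)) < cutoff:
                continue
            pct = orthology.pairwise_identity(rec.sequence, rep)
            if pct >= cutoff:
                fam.members.append(rec)
                fam.identities.append(pct)
                by_exact.setdefault(rec.sequence, idx)
                placed = True
                break
        if not placed:
            families.append(GeneFamily(f"GF{len(families)+1:05d}", rec, [rec], [100.0]))
            by_exact[rec.sequence] = len(families) - 1
    return families


@dataclass
class PresenceMatrix:
    """Binary strain x family matrix (1 = the strain has >= 1 member)."""

    matrix: pd.DataFrame

    def __post_init__(self):
        vals = self.matrix.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0/1")
        self.matrix = self.matrix.astype(int)

    @property
    def strains(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def families(self) -> list[str]:
        return list(self.matrix.columns)

    def row_sums(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    def pan_size(self) -> int:
        return int((self.matrix.sum(axis=0) > 0).sum())

    def core_size(self) -> int:
        return int((self.matrix.sum(axis=0) == len(self.matrix)).sum())


def build_presence_matrix(families: list[GeneFamily], strains: list[str]) -> PresenceMatrix:
    """Entry (s, f) = 1 iff family f has a member from strain s (paralogs count once)."""
    fids = [f.family_id for f in families]
    mat = pd.DataFrame(0, index=pd.Index(strains, name="strain"), columns=pd.Index(fids, name="family"), dtype=int)
    for fam in families:
        for s in fam.strains:
            if s in mat.index:
                mat.loc[s, fam.family_id] = 1
    return PresenceMatrix(mat)


def order_strains_by_shared(matrix: PresenceMatrix) -> list[str]:
    """Strains by decreasing family count; ties lexicographic by strain id."""
    sums = matrix.row_sums()
    return sorted(matrix.strains, key=lambda s: (-sums[s], s))


@dataclass
class CoreCurve:
    ordering: list[str]
    sizes: list[int]  # k-th value: families shared by the first k strains


def core_genome_curve(matrix: PresenceMatrix, ordering: list[str] | None = None) -> CoreCurve:
    """Running intersection of family content along the strain ordering."""
    if ordering is None:
        ordering = order_strains_by_shared(matrix)
    if sorted(ordering) != sorted(matrix.strains):
        raise ValueError("ordering must be a permutation of the matrix's strains")
    rows = matrix.matrix.loc[ordering].to_numpy(dtype=bool)
    running = np.logical_and.accumulate(rows, axis=0)
    return CoreCurve(list(ordering), running.sum(axis=1).astype(int).tolist())


def cluster_strain_blocks(matrix: PresenceMatrix, n_blocks: int) -> dict[str, int]:
    """Agglomerative Jaccard/average-linkage clustering of strain presence rows.

    Returns strain -> block label (1-based, relabelled in order of first
    appearance along the strain list for determinism).
    """
    strains = matrix.strains
    if n_blocks > len(strains):
        raise ValueError(f"n_blocks={n_blocks} exceeds the {len(strains)} strains")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rows = matrix.matrix.to_numpy(dtype=bool)
    if n_blocks > 1 and (rows == rows[0]).all():
        raise ValueError("all strain rows identical: the panel cannot be divided into more than one block")
    dist = pdist(rows, metric="jaccard")
    labels = fcluster(average(dist), t=n_blocks, criterion="maxclust")
    remap: dict[int, int] = {}
    out = {}
    for s, lab in zip(strains, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[s] = remap[lab]
    return out


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def read_proteomes_fasta(paths: list[str | Path]) -> list[ProteinRecord]:
    """Read multi-FASTA files with ``strain|gene`` headers."""
    from Bio import SeqIO

    records = []
    for path in paths:
        for rec in SeqIO.parse(str(path), "fasta"):
            strain, _, gene = rec.id.partition("|")
            records.append(ProteinRecord(strain, gene or rec.id, str(rec.seq)))
    return records


def families_table(families: list[GeneFamily]) -> pd.DataFrame:
    rows = []
    for fam in families:
        for m, pct in zip(fam.members, fam.identities):
            rows.append({"family_id": fam.family_id, "strain": m.strain, "gene": m.gene, "identity_to_rep": pct})
    return pd.DataFrame(rows, columns=["family_id", "strain", "gene", "identity_to_rep"])
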