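"""Alleleome analysis: allele enumeration, dominance, substitution character,
and major/minor clade splits.

An allele is a unique amino-acid sequence within a gene family; its
frequency is the number of strains carrying it.  Alleles are ranked by
strain count and named by it — alleles sharing a count get suffixes
``count-1``, ``count-2``, … in rank order.  For each family with at least
three alleles, a neighbor-joining tree on p-distance, midpoint-rooted,
splits the alleles into a major and a minor clade.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from . import orthology
from .pangenome import GeneFamily

#: Physico-chemical residue groups for conservative-substitution calls:
#: hydrophobic/aliphatic, aromatic, hydroxyl, amide, acidic, basic, and the
#: structurally special glycine and proline on their own.
CONSERVATIVE_GROUPS = ["AVLIMC", "FWY", "ST", "NQ", "DE", "KRH", "G", "P"]
_GROUP_OF = {aa: i for i, grp in enumerate(CONSERVATIVE_GROUPS) for aa in grp}


@dataclass
class Allele:
    family_id: str
    name: str
    sequence: str
    strains: frozenset[str]

    @property
    def strain_count(self) -> int:
        return len(self.strains)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AlleleTable:
    """Per-family alleles sorted by decreasing strain count."""

    alleles: dict[str, list[Allele]]

    def allele_count(self, family_id: str) -> int:
        return len(self.alleles[family_id])

    def dominant(self, family_id: str) -> Allele:
        return self.alleles[family_id][0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fid in self.alleles:
            for a in self.alleles[fid]:
                rows.append(
                    {
                        "family_id": fid,
                        "allele": a.name,
                        "strain_count": a.strain_count,
                        "length": a.length,
                        "strains": ";".join(sorted(a.strains)),
                    }
                )
        return pd.DataFrame(rows, columns=["family_id", "allele", "strain_count", "length", "strains"])


def build_allele_table(families: list[GeneFamily]) -> AlleleTable:
    """Group identical member sequences per family and rank by strain count.

    A strain carrying two distinct paralogous sequences contributes to both
    alleles' strain sets; counts are distinct-strain counts.  Ties in count
    are broken by sequence lexicographic order.
    """
    table: dict[str, list[Allele]] = {}
    for fam in families:
        strains_of: dict[str, set[str]] = {}
        for m in fam.members:
            strains_of.setdefault(m.sequence, set()).add(m.strain)
        ranked = sorted(strains_of.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        counts = [len(s) for _, s in ranked]
        alleles = []
        for i, (seq, strains) in enumerate(ranked):
            count = len(strains)
            if counts.count(count) > 1:
                suffix = sum(1 for c in counts[: i + 1] if c == count)
                name = f"{count}-{suffix}"
            else:
                name = str(count)
            alleles.append(Allele(fam.family_id, name, seq, frozenset(strains)))
        table[fam.family_id] = alleles
    return AlleleTable(table)


def dominant_alleles(table: AlleleTable, n_strains: int, fraction: float = 0.5) -> list[tuple[str, Allele]]:
    """Alleles carried by strictly more than ``fraction`` of the strains."""
    if n_strains < 1:
        raise ValueError("n_strains must be >= 1")
    cutoff = fraction * n_strains
    out = []
    for fid in table.alleles:
        for allele in table.alleles[fid]:
            if allele.strain_count > cutoff:
                out.append((fid, allele))
    return out


def allele_length_summary(table: AlleleTable, subset: list[tuple[str, Allele]]) -> tuple[float, float]:
    """Mean and median residue length over a subset of alleles."""
    if not subset:
        raise ValueError("empty allele subset")
    lengths = [a.length for _, a in subset]
    return float(np.mean(lengths)), float(statistics.median(lengths))


def _aligned_columns(a: str, b: str) -> list[tuple[str, str]]:
    """Column pairs of the optimal global alignment ('-' marks a gap)."""
    if len(a) == len(b):
        return list(zip(a, b))
    alignment = orthology._aligner().align(a, b)[0]
    sa, sb = str(alignment[0]), str(alignment[1])
    return list(zip(sa, sb))


def substitution_profile(family_alleles: list[Allele]) -> dict[str, int]:
    """Conservative vs non-conservative substitution counts against the dominant.

    The first (highest-count) allele is the reference.  Each aligned column
    where both alleles carry a residue and the residues differ is
    conservative iff both residues fall in the same physico-chemical group;
    indel columns are tallied separately and excluded from the substitution
    counts.
    """
    if len(family_alleles) < 2:
        raise ValueError("substitution profile needs >= 2 alleles")
    dominant = family_alleles[0]
    cons = noncons = indels = 0
    for allele in family_alleles[1:]:
        for ra, rb in _aligned_columns(dominant.sequence, allele.sequence):
            if ra == "-" or rb == "-":
                indels += 1
            elif ra != rb:
                if _GROUP_OF.get(ra, -1) == _GROUP_OF.get(rb, -2):
                    cons += 1
                else:
                    noncons += 1
    return {"conservative": cons, "non_conservative": noncons, "indel_columns": indels}


def p_distance(a: str, b: str) -> float:
    """Fraction of differing residue pairs among aligned residue columns."""
    diffs = total = 0
    for ra, rb in _aligned_columns(a, b):
        if ra == "-" or rb == "-":
            continue
        total += 1
        if ra != rb:
            diffs += 1
    if total == 0:
        return 1.0
    return diffs / total


def nj_tree(distances: np.ndarray, names: list[str]):
    """Neighbor-joining tree from a symmetric distance matrix.

    Branch lengths left undefined by the join (the root edge) are set to 0
    so downstream midpoint rooting is total.
    """
    tree = nj(DistanceMatrix(distances, names))
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return tree


def _midpoint_root(tree):
    """Root on the edge holding the midpoint of the longest tip-to-tip path.

    Rooting is always placed strictly inside an edge (nudged by 1e-12 when
    the midpoint falls exactly on a node), so the root bifurcates and the
    two clades are well defined even for star-like trees.
    """
    tips = sorted(tree.tips(), key=lambda t: t.name)
    best = (-1.0, None, None)
    for i, a in enumerate(tips):
        for b in tips[i + 1 :]:
            d = a.distance(b)
            if d > best[0]:
                best = (d, a, b)
    diameter, a, b = best
    if diameter <= 0:
        raise ValueError("all alleles are equidistant at zero: no clade structure")
    half = diameter / 2.0
    lca = tree.lca([a, b])

    tol = 1e-9 * diameter  # midpoint exactly on a node: prefer the tip-side edge

    def find_edge(start):
        cum, node = 0.0, start
        while node is not lca:
            length = node.length or 0.0
            if cum + length >= half - tol:
                return node, half - cum, length
            cum += length
            node = node.parent
        return None

    hit = find_edge(a) or find_edge(b)
    node, above, length = hit
    if length < 1e-9:  # inflate a zero-length edge so the root fits inside it
        node.length = length = 1e-9
    above = min(max(above, 1e-12), length - 1e-12)
    return tree.root_at(node, above=above)


@dataclass
class CladeSplit:
    family_id: str
    newick: str
    major: list[str]  # allele names
    minor: list[str]

    @property
    def major_fraction(self) -> float:
        return len(self.major) / (len(self.major) + len(self.minor))


def allele_tree(family_alleles: list[Allele]) -> CladeSplit:
    """NJ tree on p-distances, midpoint-rooted; the root's subtrees are clades.

    The major clade is the one with more alleles (ties broken toward the
    larger total strain count, then lexicographically smallest allele-name
    set).  Branch lengths are in substitutions per site.
    """
    if len(family_alleles) < 3:
        raise ValueError("a clade split needs >= 3 alleles")
    names = [a.name for a in family_alleles]
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = p_distance(family_alleles[i].sequence, family_alleles[j].sequence)
    tree = nj_tree(dm, names)
    rooted = _midpoint_root(tree)
    clades = [sorted(t.name for t in child.tips()) or [child.name] for child in rooted.children]
    count_of = {a.name: a.strain_count for a in family_alleles}

    def rank(clade):
        return (len(clade), sum(count_of[x] for x in clade), [-ord(c) for c in "".join(clade)])

    major, minor = sorted(clades, key=rank, reverse=True)
    return CladeSplit(family_alleles[0].family_id, _to_newick(rooted), sorted(major), sorted(minor))


def _to_newick(tree) -> str:
    import io

    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
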