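"""Alignment-column screen for category-divergent amino-acid composition.

For each column of a protein multiple alignment, build the set of amino acids
observed in each phenotype category (species with a gap are ignored at that
site), score between-category similarity as the minimum pairwise Jaccard
index, and flag low-similarity sites whose signal traces to a single clade
via a Fitch small-parsimony origin count.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass

from Bio import SeqIO

from .categories import PhenotypeVector
from .phylo import Phylogeny

__all__ = [
    "SiteCategoryProfile",
    "read_alignment",
    "profile_sites",
    "site_similarity",
    "fitch_changes",
    "screen_sites",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = set("-.*X")


@dataclass
class SiteCategoryProfile:
    """Per-category amino-acid sets at one alignment column (1-based)."""

    site: int
    sets: dict[str, frozenset[str]]       # category -> residues (gaps excluded)
    counts: dict[str, dict[str, int]]     # category -> residue -> count
    residues: dict[str, str]              # species -> residue ('' when gapped)

    def nonempty(self) -> dict[str, frozenset[str]]:
        return {c: s for c, s in self.sets.items() if s}


def read_alignment(source: str | io.TextIOBase) -> dict[str, str]:
    """FASTA protein alignment as species -> row; rows must share one length."""
    if isinstance(source, str):
        source = io.StringIO(source)
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(source, "fasta")}
    if not rows:
        raise ValueError("no FASTA records found")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValueError(f"alignment rows differ in length: {sorted(lengths)}")
    return rows


def profile_sites(
    alignment: dict[str, str], pheno: PhenotypeVector
) -> list[SiteCategoryProfile]:
    """One category profile per alignment column."""
    unknown = set(alignment) - set(pheno.assignments)
    if unknown:
        raise ValueError(f"alignment species missing from phenotype table: {sorted(unknown)}")
    length = len(next(iter(alignment.values())))
    bad = {
        ch
        for seq in alignment.values()
        for ch in seq
        if ch not in AMINO_ACIDS and ch not in GAP_CHARS
    }
    if bad:
        raise ValueError(f"unknown residue characters: {sorted(bad)}")
    profiles = []
    for col in range(length):
        sets: dict[str, set[str]] = {c: set() for c in pheno.categories}
        counts: dict[str, dict[str, int]] = {c: {} for c in pheno.categories}
        residues: dict[str, str] = {}
        for sp, seq in alignment.items():
            ch = seq[col]
            cat = pheno.assignments[sp]
            if ch in GAP_CHARS:
                residues[sp] = ""
                continue
            residues[sp] = ch
            sets[cat].add(ch)
            counts[cat][ch] = counts[cat].get(ch, 0) + 1
        profiles.append(
            SiteCategoryProfile(
                site=col + 1,
                sets={c: frozenset(s) for c, s in sets.items()},
                counts=counts,
                residues=residues,
            )
        )
    return profiles


def site_similarity(profile: SiteCategoryProfile, method: str = "min") -> float:
    """Between-category set similarity: minimum (default) or mean pairwise Jaccard."""
    sets = list(profile.nonempty().values())
    if len(sets) < 2:
        raise ValueError("site similarity needs >= 2 categories with residues")
    jaccards = [
        len(a & b) / len(a | b) for a, b in itertools.combinations(sets, 2)
    ]
    if method == "min":
        return float(min(jaccards))
    if method == "mean":
        return float(sum(jaccards) / len(jaccards))
    raise ValueError("method must be 'min' or 'mean'")


def fitch_changes(tree: Phylogeny, tip_values: dict[str, int]) -> int:
    """Minimum state changes (Fitch small parsimony) for tip values on the tree.

    Tips absent from ``tip_values`` are treated as missing and contribute a
    wildcard state set.
    """
    sets: dict[int, frozenset[int]] = {}
    universe = frozenset(set(tip_values.values()) or {0})
    changes = 0
    for node in tree.postorder():
        if tree.is_tip(node):
            label = tree.labels[node]
            val = tip_values.get(label)
            sets[node] = frozenset([val]) if val is not None else universe
        else:
            inter = universe
            for c in tree.children[node]:
                inter = inter & sets[c]
            if inter:
                sets[node] = inter
            else:
                union = frozenset()
                for c in tree.children[node]:
                    union = union | sets[c]
                sets[node] = union
                changes += 1
    return changes


@dataclass
class SiteCandidate:
    site: int                    # 1-based alignment column
    similarity: float
    focal_category: str
    focal_residues: frozenset[str]
    origins: int
    clade_confounded: bool       # True when the focal residues trace to one clade
    ref_site: int | None = None  # 1-based ungapped position in the reference row


def screen_sites(
    alignment: dict[str, str],
    pheno: PhenotypeVector,
    tree: Phylogeny,
    threshold: float = 0.2,
    similarity_method: str = "min",
    reference: str | None = None,
) -> list[SiteCandidate]:
    """Sites whose between-category similarity is at or below ``threshold``.

    Each retained site is annotated with a clade-independence score: for the
    category with the most invariant (smallest) residue set, count the
    minimum number of phylogenetic origins of its residues by Fitch parsimony
    on presence/absence across all ungapped species.  Sites with a single
    origin are flagged as clade-confounded rather than convergent.
    """
    missing = set(alignment) - tree.tip_labels
    if missing:
        raise ValueError(f"alignment species missing from tree: {sorted(missing)}")
    if reference is not None and reference not in alignment:
        raise ValueError(f"reference species {reference!r} not in alignment")
    ref_coord: dict[int, int] = {}
    if reference is not None:
        pos = 0
        for col, ch in enumerate(alignment[reference], start=1):
            if ch not in GAP_CHARS:
                pos += 1
                ref_coord[col] = pos
    profiles = profile_sites(alignment, pheno)
    out: list[SiteCandidate] = []
    for prof in profiles:
        nonempty = prof.nonempty()
        if len(nonempty) < 2:
            continue
        sim = site_similarity(prof, method=similarity_method)
        if sim > threshold:
            continue
        # most invariant category: smallest residue set, registry order ties
        focal_cat = min(
            nonempty, key=lambda c: (len(nonempty[c]), pheno.index_of(c))
        )
        focal = nonempty[focal_cat]
        presence = {
            sp: int(res in focal)
            for sp, res in prof.residues.items()
            if res
        }
        origins = _origin_count(tree, presence)
        out.append(
            SiteCandidate(
                site=prof.site, similarity=sim, focal_category=focal_cat,
                focal_residues=focal, origins=origins,
                clade_confounded=origins < 2,
                ref_site=ref_coord.get(prof.site),
            )
        )
    return out


def _origin_count(tree: Phylogeny, presence: dict[str, int]) -> int:
    """Fitch change count of the focal residue's presence/absence pattern."""
    if all(v == 1 for v in presence.values()):
        return 1  # residue universal: a single (root) origin
    return fitch_changes(tree, presence)
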