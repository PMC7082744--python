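"""Seed-sequence analysis and hit-set integration.

Mature miRNA sequences are handled as RNA strings; the *seed* is the
6-mer at positions 2-7 from the 5' end, the primary determinant of
target binding.  This module reconciles annotation between libraries,
categorises motif positions (seed 2-7 vs shifted 3-8), tests motif
over-representation in hit sets with an exact Fisher test, intersects
hit sets across screens, summarises positional Z-score groups, builds
per-position consensus profiles, and ranks target genes by the number
of distinct miRNAs hitting them.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

RNA_ALPHABET = frozenset("ACGU")
SEED_START = 2  # 1-based, inclusive
SEED_LENGTH = 6


def normalize_rna(sequence: str) -> str:
    """Uppercase, convert T to U, and validate the RNA alphabet."""
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA: canonical name, normalized RNA sequence, derived seed."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if len(self.sequence) < SEED_START + SEED_LENGTH - 1:
            raise ValueError(
                f"{self.name}: sequence too short ({len(self.sequence)} nt) to hold a seed"
            )

    @property
    def seed(self) -> str:
        return extract_seed(self.sequence)


def extract_seed(sequence: str) -> str:
    """Return the seed: the 6-mer at 1-based positions 2-7 from the 5' end."""
    seq = normalize_rna(sequence)
    if len(seq) < SEED_START + SEED_LENGTH - 1:
        raise ValueError(f"sequence length {len(seq)} < 7; no seed can be extracted")
    return seq[SEED_START - 1 : SEED_START - 1 + SEED_LENGTH]


# ---------------------------------------------------------------------------
# annotation reconciliation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationMap:
    """Result of matching query sequences against a reference by mature sequence."""

    matches: dict[str, list[str]]          # query name -> reference name(s)
    unmatched: list[str]                   # query names with no reference match
    ambiguous: list[str] = field(default_factory=list)  # queries with >1 match


def read_fasta(path: str | Path) -> list[MiRNARecord]:
    """Read a mature-sequence FASTA (DNA or RNA alphabet) into records."""
    records = [MiRNARecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[MiRNARecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n{rec.sequence}\n")


def reconcile_names(
    queries: Sequence[MiRNARecord],
    reference: Sequence[MiRNARecord] | str | Path,
) -> AnnotationMap:
    """Match query records to reference nomenclature by exact mature sequence.

    Sequences are compared after case/T-to-U normalization (which
    ``MiRNARecord`` applies on construction).  A query sequence present
    under several reference names is matched to all of them and flagged
    ambiguous.
    """
    if isinstance(reference, (str, Path)):
        reference = read_fasta(reference)
    if not reference:
        raise ValueError("empty reference")
    by_seq: dict[str, list[str]] = {}
    for ref in reference:
        by_seq.setdefault(ref.sequence, []).append(ref.name)
    matches: dict[str, list[str]] = {}
    unmatched: list[str] = []
    ambiguous: list[str] = []
    for q in queries:
        names = by_seq.get(q.sequence)
        if names is None:
            unmatched.append(q.name)
        else:
            matches[q.name] = list(names)
            if len(names) > 1:
                ambiguous.append(q.name)
    return AnnotationMap(matches=matches, unmatched=unmatched, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# motif position categories
# ---------------------------------------------------------------------------

CATEGORY_POS2_7 = "pos2_7"
CATEGORY_POS3_8 = "pos3_8"
CATEGORY_OTHER = "other_position"
CATEGORY_ABSENT = "absent"


@dataclass(frozen=True)
class PositionalCategory:
    category: str
    starts: tuple[int, ...]  # all 1-based match start positions


def motif_position(sequence: str, motif: str) -> PositionalCategory:
    """Locate all exact matches of a 6-mer motif and categorise the sequence.

    A match starting at position 2 takes priority (seed position) over a
    match at position 3; any other match position is ``other_position``.
    """
    if len(motif) != SEED_LENGTH:
        raise ValueError(f"motif must be {SEED_LENGTH} nt, got {len(motif)}")
    motif = normalize_rna(motif)
    seq = normalize_rna(sequence)
    starts = tuple(
        i + 1 for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif
    )
    if 2 in starts:
        cat = CATEGORY_POS2_7
    elif 3 in starts:
        cat = CATEGORY_POS3_8
    elif starts:
        cat = CATEGORY_OTHER
    else:
        cat = CATEGORY_ABSENT
    return PositionalCategory(category=cat, starts=starts)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b, c, d) = (hit&motif, hit&no-motif, no-hit&motif, no-hit&no-motif)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency counts must be nonnegative integers")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns ``(odds_ratio, p)``.  With margins fixed the count in cell
    ``a`` is hypergeometric; the two-sided p-value sums the probabilities
    of all tables whose probability does not exceed the observed one
    (with a 1 + 1e-7 relative slack for floating-point ties).  The odds
    ratio is the sample ratio ad/bc (inf when bc = 0 and ad > 0, nan for
    0/0).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    if n == 0:
        raise ValueError("all-zero contingency table")
    row1 = a + b
    col1 = a + c
    rv = stats.hypergeom(n, col1, row1)
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(1.0, p)
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    return odds, p


@dataclass
class EnrichmentResult:
    table: ContingencyTable2x2
    odds_ratio: float
    pvalue: float
    mode: str
    motif: str


MODE_SEED = "seed2_7"
MODE_ANYWHERE = "anywhere"


def _carries_motif(record: MiRNARecord, motif: str, mode: str) -> bool:
    if mode == MODE_SEED:
        return record.seed == normalize_rna(motif)
    if mode == MODE_ANYWHERE:
        return normalize_rna(motif) in record.sequence
    raise ValueError(f"unknown mode {mode!r}")


def seed_enrichment(
    hits: Iterable[str],
    universe: Sequence[MiRNARecord],
    motif: str = "AAGUGC",
    mode: str = MODE_SEED,
) -> EnrichmentResult:
    """Test over-representation of a motif among hits within a miRNA universe."""
    hit_set = set(hits)
    names = {r.name for r in universe}
    extra = hit_set - names
    if extra:
        raise ValueError(f"hits not in universe: {sorted(extra)[:5]}")
    a = b = c = d = 0
    for rec in universe:
        carries = _carries_motif(rec, motif, mode)
        if rec.name in hit_set:
            a, b = a + carries, b + (not carries)
        else:
            c, d = c + carries, d + (not carries)
    table = ContingencyTable2x2(a, b, c, d)
    if a + c == 0:  # no motif carriers at all: no evidence either way
        return EnrichmentResult(table, math.nan, 1.0, mode, motif)
    odds, p = fisher_exact(table)
    return EnrichmentResult(table, odds, p, mode, motif)


# ---------------------------------------------------------------------------
# hit-set intersection (Venn partition)
# ---------------------------------------------------------------------------

def intersect_hits(sets: Mapping[str, Iterable[str]]) -> tuple[pd.DataFrame, dict[str, int]]:
    """Membership table and Venn-partition counts for two or more named sets.

    Returns a boolean membership DataFrame (rows = union of members,
    one column per set name) and a dict mapping membership patterns
    (e.g. ``"110"`` in column order) to the number of members in that
    exclusive region.  The all-ones pattern is the full intersection.
    """
    names = list(sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    materialised = {k: set(v) for k, v in sets.items()}
    universe = sorted(set().union(*materialised.values()))
    member = pd.DataFrame(
        {k: [m in materialised[k] for m in universe] for k in names},
        index=pd.Index(universe, name="mir_name"),
    )
    counts = {
        "".join(map(str, map(int, pattern))): int(n)
        for pattern, n in Counter(map(tuple, member.values)).items()
    }
    return member, counts


def intersection_members(membership: pd.DataFrame) -> list[str]:
    """Members belonging to every set of a membership table."""
    return sorted(membership.index[membership.all(axis=1)])


# ---------------------------------------------------------------------------
# positional group statistics and consensus
# ---------------------------------------------------------------------------

def positional_group_stats(
    scores: pd.DataFrame,
    records: Sequence[MiRNARecord],
    motif: str = "AAGUGC",
) -> pd.DataFrame:
    """Mean averaged Z per motif-position category per screen.

    ``scores`` needs columns ``screen``, ``mir_name``, ``z_avg``.
    Categories with no members are simply absent from the output.
    """
    cats = {r.name: motif_position(r.sequence, motif).category for r in records}
    df = scores.copy()
    df["category"] = df["mir_name"].map(cats)
    df = df.dropna(subset=["category"])
    out = (
        df.groupby(["screen", "category"], as_index=False)
        .agg(mean_z=("z_avg", "mean"), n=("z_avg", "size"))
        .sort_values(["screen", "category"], ignore_index=True)
    )
    return out


def consensus_profile(
    sequences: Sequence[str], threshold: float = 0.8
) -> tuple[pd.DataFrame, dict[int, str]]:
    """Per-position base-frequency matrix and high-consensus positions.

    Positions are 1-based from the 5' end; ragged lengths are truncated
    to the shortest sequence.  A position is a consensus position when
    its modal base frequency reaches ``threshold``.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    seqs = [normalize_rna(s) for s in sequences]
    length = min(len(s) for s in seqs)
    bases = sorted(RNA_ALPHABET)
    freq = np.zeros((len(bases), length))
    for s in seqs:
        for j in range(length):
            freq[bases.index(s[j]), j] += 1
    freq /= len(seqs)
    profile = pd.DataFrame(freq, index=bases, columns=range(1, length + 1))
    consensus = {
        int(pos): bases[int(np.argmax(profile[pos].to_numpy()))]
        for pos in profile.columns
        if profile[pos].max() >= threshold
    }
    return profile, consensus


# ---------------------------------------------------------------------------
# target ranking
# ---------------------------------------------------------------------------

def target_ranking(
    interactions: pd.DataFrame,
    mir_subset: Iterable[str],
    top_k: int | None = None,
) -> pd.DataFrame:
    """Rank genes by the number of distinct subset miRNAs targeting them.

    ``interactions`` holds (mir, gene) pairs; duplicates count once.
    Ties are broken alphabetically by gene name.
    """
    subset = set(mir_subset)
    pairs = interactions[["mir", "gene"]].drop_duplicates()
    pairs = pairs[pairs["mir"].isin(subset)]
    counts = (
        pairs.groupby("gene")["mir"]
        .nunique()
        .rename("n_mirs")
        .reset_index()
        .sort_values(["n_mirs", "gene"], ascending=[False, True], ignore_index=True)
    )
    if top_k is not None:
        counts = counts.head(top_k).reset_index(drop=True)
    return counts
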