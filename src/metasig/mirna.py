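"""miRNA seed-site scanner.

Locates putative miRNA target sites in mRNA/3'UTR sequences by sliding a
seed-length window along the target (read 5'->3') and pairing it
antiparallel against the seed region of the mature miRNA: target position
``start + seed_length - 1 - j`` pairs with seed position ``j``.  A site is
declared when at least ``min_complementary`` of the ``seed_length``
positions are complementary, where up to ``max_gu`` G:U wobble pairs count
as complementary (further G:U pairs count as mismatches).  Defaults are an
8-nt seed, >=7 complementary, and at most one G:U.

Sequences may be given as DNA (T) or RNA (U); T is normalized to U.  Only
the given strand is scanned, and no thermodynamic or conservation scoring
is applied — the rule is purely combinatorial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSpec",
    "SeedMatch",
    "pair_class",
    "scan_seed_sites",
    "scan_fasta",
    "matches_to_frame",
    "write_matches_tsv",
    "write_matches_bed",
    "reverse_complement_rna",
]

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "U"), ("U", "G")}
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def normalize_rna(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase and map T->U; any base outside {A,C,G,U} is a hard error."""
    seq = str(sequence).upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in {context}")
    return seq


def reverse_complement_rna(sequence: str) -> str:
    seq = normalize_rna(sequence)
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def pair_class(target_base: str, mirna_base: str) -> str:
    """Classify one target:miRNA base pair as 'WC', 'GU' or 'MISMATCH'."""
    pair = (target_base, mirna_base)
    for b in pair:
        if b not in "ACGU":
            raise ValueError(f"invalid base {b!r}; expected A/C/G/U")
    if pair in _WC:
        return "WC"
    if pair in _GU:
        return "GU"
    return "MISMATCH"


@dataclass(frozen=True)
class SeedSpec:
    """Seed definition of a mature miRNA.

    The seed is the first ``seed_length`` nucleotides of the mature miRNA
    5'->3' starting at ``seed_offset`` (1-based; both offset-1 and offset-2
    seed conventions exist in the field, default 1).
    """

    mirna_id: str
    mirna_sequence: str
    seed_length: int = 8
    min_complementary: int = 7
    max_gu: int = 1
    seed_offset: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mirna_sequence", normalize_rna(self.mirna_sequence, context="miRNA")
        )
        if self.seed_offset < 1:
            raise ValueError("seed_offset is 1-based and must be >= 1")
        if self.seed_offset - 1 + self.seed_length > len(self.mirna_sequence):
            raise ValueError("seed extends beyond the miRNA sequence")
        if not (0 <= self.min_complementary <= self.seed_length):
            raise ValueError("min_complementary must be in [0, seed_length]")
        if self.max_gu < 0:
            raise ValueError("max_gu must be >= 0")

    @property
    def seed_sequence(self) -> str:
        """The seed region, 5'->3'."""
        start = self.seed_offset - 1
        return self.mirna_sequence[start : start + self.seed_length]


@dataclass(frozen=True)
class SeedMatch:
    """One putative target site (0-based half-open on the target, 5'->3')."""

    sequence_id: str
    start: int
    end: int
    n_watson_crick: int
    n_gu: int
    n_mismatch: int
    window: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.window):
            raise ValueError("interval length does not match window")
        if self.n_watson_crick + self.n_gu + self.n_mismatch != len(self.window):
            raise ValueError("pair counts do not sum to seed length")


def scan_seed_sites(sequence_id: str, target: str, spec: SeedSpec) -> list[SeedMatch]:
    """Scan one target sequence for putative seed-match sites.

    All qualifying windows are reported (overlaps included), sorted by
    start; each window is reported at most once.
    """
    seq = normalize_rna(target, context=f"target {sequence_id!r}")
    seed = spec.seed_sequence
    slen = spec.seed_length
    if len(seq) < slen:
        raise ValueError(f"target {sequence_id!r} shorter than the seed length")
    matches: list[SeedMatch] = []
    for start in range(len(seq) - slen + 1):
        window = seq[start : start + slen]
        n_wc = n_gu = 0
        for j in range(slen):
            cls = pair_class(window[slen - 1 - j], seed[j])
            if cls == "WC":
                n_wc += 1
            elif cls == "GU":
                n_gu += 1
        if n_wc + min(n_gu, spec.max_gu) >= spec.min_complementary:
            matches.append(
                SeedMatch(
                    sequence_id=sequence_id,
                    start=start,
                    end=start + slen,
                    n_watson_crick=n_wc,
                    n_gu=n_gu,
                    n_mismatch=slen - n_wc - n_gu,
                    window=window,
                )
            )
    return matches


def scan_fasta(path, spec: SeedSpec) -> list[SeedMatch]:
    """Scan every record of a FASTA file; records shorter than the seed are
    skipped with a warning, and scanning never crosses record boundaries."""
    matches: list[SeedMatch] = []
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seq = str(record.seq)
        if len(seq) < spec.seed_length:
            logger.warning(
                "skipping record %s: length %d < seed length %d",
                record.id, len(seq), spec.seed_length,
            )
            continue
        matches.extend(scan_seed_sites(record.id, seq, spec))
    if n_records == 0:
        raise ValueError(f"no FASTA records in {path}")
    return matches


def matches_to_frame(matches: list[SeedMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence_id": m.sequence_id,
                "start": m.start,
                "end": m.end,
                "window": m.window,
                "n_wc": m.n_watson_crick,
                "n_gu": m.n_gu,
                "n_mismatch": m.n_mismatch,
            }
            for m in matches
        ],
        columns=["sequence_id", "start", "end", "window", "n_wc", "n_gu", "n_mismatch"],
    )


def write_matches_tsv(matches: list[SeedMatch], path) -> None:
    """TSV report; start/end are 0-based half-open (stated in the header)."""
    df = matches_to_frame(matches)
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based, half-open, target strand 5'->3'\n")
        df.to_csv(fh, sep="\t", index=False)


def write_matches_bed(matches: list[SeedMatch], spec: SeedSpec, path) -> None:
    """BED6: name = miRNA id, score = number of Watson-Crick pairs."""
    with open(path, "w") as fh:
        for m in matches:
            fh.write(
                f"{m.sequence_id}\t{m.start}\t{m.end}\t{spec.mirna_id}"
                f"\t{m.n_watson_crick}\t+\n"
            )
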