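"""Paired-end read processing: from FASTQ to per-variant flipping counts.

Reads are paired by ID, filtered for long ambiguous runs, anchored on a
10-bp constant region, demultiplexed by a dual 6-bp index combination,
assigned a discriminator state by matching the attP (unflipped) or attR
(flipped) site, and reduced to per-RBS, per-sample flipped/unflipped
counts.  Variants with too many CDS mismatches or too few reads are then
removed.  All sequence matching is Hamming distance on aligned windows
(no indels), scanning every window and keeping the minimum-distance,
leftmost-tie-break hit.

Amplicon layout (both mates stored in amplicon sense orientation):

    forward read (70 nt): [5' pad 20 nt][RBS 17 nt][ATG + CDS 30 nt]
    reverse read (50 nt): [index1 6][constant 10][index2 6][spacer 4]
                          [att site 17][3' pad 7]
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import zip_longest

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FWD_PAD",
    "CDS_REF",
    "REV_SPACER",
    "REV_PAD",
    "RBS_LENGTH",
    "SiteDefinitions",
    "VariantProfile",
    "FilterStats",
    "hamming",
    "filter_ambiguous",
    "match_constant_region",
    "load_index_table",
    "demultiplex",
    "call_discriminator_state",
    "extract_rbs",
    "filter_cds_mutants",
    "apply_read_threshold",
    "build_profiles",
    "profiles_to_frame",
]

RBS_LENGTH = 17
#: fixed 5'-UTR context upstream of the randomized RBS on the forward mate
FWD_PAD = "TTCACACAGGAAACAGACTA"
#: start codon plus the first 30 nt of the recombinase CDS; the RBS is the
#: 17 nt immediately 5' of this reference
CDS_REF = "ATG" + "CGTGCCCTGGTTGTCATCCGTCTGTCCCGT"
REV_SPACER = "ACTG"
REV_PAD = "GATCGAT"

# reverse-mate offsets relative to the constant-region anchor
_IDX1_OFF = -6          # index1 ends where the constant region starts
_IDX2_OFF = 10          # index2 starts right after the constant region
_ATT_OFF = 10 + 6 + len(REV_SPACER)   # att site after index2 + spacer
_ATT_LEN = 17


@dataclass(frozen=True)
class SiteDefinitions:
    """Reference sequences and tolerances for read matching."""

    constant_region: str = "GAGCTCGCAT"
    attP_site: str = "GGGTTTGTACCGTACAC"
    attR_site: str = "GCCCGGATGATCCTGAC"
    max_mismatches: int = 3
    rbs_length: int = RBS_LENGTH

    def __post_init__(self):
        if len(self.attP_site) != len(self.attR_site):
            raise ValueError("attP and attR sites must have equal length")
        d = hamming(self.attP_site, self.attR_site)
        if d <= 2 * self.max_mismatches:
            raise ValueError(
                f"attP/attR Hamming distance {d} must exceed "
                f"2 x max_mismatches = {2 * self.max_mismatches} for "
                "unambiguous state calls"
            )


@dataclass
class VariantProfile:
    """Per-RBS flipped/unflipped counts at each sample.

    ``counts`` maps sample label -> (n_unflipped, n_flipped).
    """

    rbs_sequence: str
    counts: dict
    cds_mismatch_fraction: float = 0.0

    def fraction_flipped(self, sample):
        u, f = self.counts[sample]
        if u + f == 0:
            raise ZeroDivisionError("no reads at this sample")
        return f / (u + f)


@dataclass
class FilterStats:
    """Read bookkeeping: how many pairs each stage removed."""

    total_pairs: int = 0
    unpaired: int = 0
    ambiguous: int = 0
    no_constant_region: int = 0
    undetermined_index: int = 0
    unknown_state: int = 0
    no_rbs_anchor: int = 0
    ambiguous_rbs: int = 0
    aggregated: int = 0
    variants_pre_filter: int = 0
    variants_cds_filtered: int = 0
    variants_below_threshold: int = 0
    variants_final: int = 0

    _READ_STAGES = (
        "unpaired", "ambiguous", "no_constant_region", "undetermined_index",
        "unknown_state", "no_rbs_anchor", "ambiguous_rbs",
    )

    def dropped_reads(self) -> int:
        return sum(getattr(self, s) for s in self._READ_STAGES)

    def conserved(self) -> bool:
        """Reads in == reads dropped per stage + reads aggregated."""
        return self.total_pairs == self.dropped_reads() + self.aggregated

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def filter_ambiguous(read: str, max_run: int = 6) -> bool:
    """Return True (keep) unless the read has a run of > max_run ambiguous
    bases; a run of exactly max_run is permitted."""
    return "N" * (max_run + 1) not in read.upper()


def match_constant_region(read: str, sites: SiteDefinitions) -> int | None:
    """Offset of the best window within ``max_mismatches`` of the constant
    region; None if no window qualifies.  Ties go to the leftmost offset."""
    return _best_window(read, sites.constant_region, sites.max_mismatches)


def _best_window(read: str, pattern: str, max_mm: int) -> int | None:
    m = len(pattern)
    best_off, best_d = None, max_mm + 1
    for off in range(len(read) - m + 1):
        d = hamming(read[off:off + m], pattern)
        if d < best_d:
            best_off, best_d = off, d
    return best_off


def load_index_table(source) -> dict:
    """Load a sample-index table (TSV with columns sample, index1, index2,
    or a mapping {(i1, i2): label}); duplicate index pairs are rejected."""
    if isinstance(source, dict):
        items = [(pair, label) for pair, label in source.items()]
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
        items = [((r.index1, r.index2), r.sample) for r in df.itertuples()]
    table = {}
    for pair, label in items:
        if pair in table:
            raise ValueError(f"duplicate index pair {pair} in index table")
        table[pair] = label
    return table


def demultiplex(index_pair: tuple[str, str], index_table: dict):
    """Exact lookup of the embedded dual index; None when undetermined."""
    return index_table.get(tuple(index_pair))


def call_discriminator_state(read: str, sites: SiteDefinitions) -> str:
    """'unflipped' if a window matches attP within tolerance, 'flipped' for
    attR, 'unknown' otherwise.  The SiteDefinitions invariant makes a
    simultaneous match impossible."""
    if _best_window(read, sites.attP_site, sites.max_mismatches) is not None:
        return "unflipped"
    if _best_window(read, sites.attR_site, sites.max_mismatches) is not None:
        return "flipped"
    return "unknown"


def extract_rbs(read: str, anchor: int, rbs_length: int = RBS_LENGTH) -> str:
    """The rbs_length bases immediately 5' of the start-codon anchor
    (anchor = index of the A of ATG), reported 5'->3'."""
    if anchor < rbs_length:
        raise ValueError(
            f"only {anchor} bases upstream of the start codon; "
            f"{rbs_length} required"
        )
    return read[anchor - rbs_length:anchor]


def filter_cds_mutants(profiles: list[VariantProfile],
                       max_fraction: float = 0.08) -> list[VariantProfile]:
    """Drop variants whose reads carry CDS mismatches in more than
    ``max_fraction`` of reads (strict inequality: exactly 8% is kept)."""
    return [p for p in profiles if p.cds_mismatch_fraction <= max_fraction]


def apply_read_threshold(profiles: list[VariantProfile],
                         theta: int) -> list[VariantProfile]:
    """Keep a variant iff it has >= theta reads at every sample."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return [
        p for p in profiles
        if all(u + f >= theta for u, f in p.counts.values())
    ]


# ---------------------------------------------------------------------------
# vectorized pipeline
# ---------------------------------------------------------------------------

def _to_matrix(seqs: list[str]):
    """Byte matrix for uniform-length sequences, else None (slow path)."""
    if not seqs:
        return None
    n0 = len(seqs[0])
    if any(len(s) != n0 for s in seqs):
        return None
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), n0
    )


def _window_dist_matrix(mat: np.ndarray, pattern: str) -> np.ndarray:
    """(n_reads, n_windows) Hamming distances of every window to pattern."""
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    m = pat.size
    nw = mat.shape[1] - m + 1
    out = np.zeros((mat.shape[0], nw), dtype=np.int16)
    for j in range(m):
        out += mat[:, j:j + nw] != pat[j]
    return out


def _best_window_vec(mat, pattern, max_mm):
    """Vectorized leftmost-minimum window match.

    Returns (offsets, distances); offset -1 where min distance > max_mm.
    """
    d = _window_dist_matrix(mat, pattern)
    off = np.argmin(d, axis=1)           # argmin returns the first minimum
    dmin = d[np.arange(d.shape[0]), off]
    off = np.where(dmin <= max_mm, off, -1)
    return off, dmin


def _read_pairs(r1_path, r2_path):
    with open(r1_path) as fh1, open(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for rec1, rec2 in zip_longest(it1, it2):
            yield rec1, rec2


def build_profiles(
    r1_path,
    r2_path,
    index_table,
    sites: SiteDefinitions | None = None,
    min_reads: int = 20,
    cds_max_fraction: float = 0.08,
    cds_ref: str = CDS_REF,
) -> tuple[list[VariantProfile], FilterStats]:
    """Run the full filtering/aggregation pipeline on a FASTQ pair.

    Stage order: pairing, ambiguity filter, constant-region selection,
    demultiplexing, discriminator-state call, RBS extraction, aggregation
    by RBS, CDS-mismatch filter, minimal read threshold.  Reads matching
    neither att site are excluded from the counts and logged separately.
    """
    sites = sites or SiteDefinitions()
    if not isinstance(index_table, dict):
        index_table = load_index_table(index_table)
    else:
        load_index_table(index_table)  # uniqueness validation
    stats = FilterStats()

    fwd, rev = [], []
    for rec1, rec2 in _read_pairs(r1_path, r2_path):
        if rec1 is None or rec2 is None:
            stats.unpaired += 1
            stats.total_pairs += 1
            continue
        (id1, s1, _), (id2, s2, _) = rec1, rec2
        stats.total_pairs += 1
        if id1.split("/")[0].split()[0] != id2.split("/")[0].split()[0]:
            stats.unpaired += 1
            continue
        if not (filter_ambiguous(s1) and filter_ambiguous(s2)):
            stats.ambiguous += 1
            continue
        fwd.append(s1.upper())
        rev.append(s2.upper())

    if not fwd:
        stats.variants_final = 0
        return [], stats

    rows = _collect_counts(fwd, rev, index_table, sites, cds_ref, stats)

    profiles = _aggregate(rows, stats)
    stats.variants_pre_filter = len(profiles)
    kept = filter_cds_mutants(profiles, cds_max_fraction)
    stats.variants_cds_filtered = len(profiles) - len(kept)
    final = apply_read_threshold(kept, min_reads)
    stats.variants_below_threshold = len(kept) - len(final)
    stats.variants_final = len(final)
    return final, stats


def _collect_counts(fwd, rev, index_table, sites, cds_ref, stats):
    """Per-read calls; returns (rbs, sample, state, cds_mismatched) rows."""
    rev_mat = _to_matrix(rev)
    fwd_mat = _to_matrix(fwd)
    if rev_mat is not None and fwd_mat is not None:
        return _collect_counts_vec(
            fwd, rev, fwd_mat, rev_mat, index_table, sites, cds_ref, stats
        )
    rows = []
    for f_read, r_read in zip(fwd, rev):
        anchor = match_constant_region(r_read, sites)
        if anchor is None:
            stats.no_constant_region += 1
            continue
        i1 = r_read[anchor + _IDX1_OFF:anchor]
        i2 = r_read[anchor + _IDX2_OFF:anchor + _IDX2_OFF + 6]
        sample = demultiplex((i1, i2), index_table) if len(i1) == 6 else None
        if sample is None:
            stats.undetermined_index += 1
            continue
        state = call_discriminator_state(r_read, sites)
        if state == "unknown":
            stats.unknown_state += 1
            continue
        cds_off = _best_window(f_read, cds_ref, len(cds_ref))
        if cds_off is None or cds_off < sites.rbs_length:
            stats.no_rbs_anchor += 1
            continue
        rbs = extract_rbs(f_read, cds_off, sites.rbs_length)
        if set(rbs) - set("ACGT"):
            stats.ambiguous_rbs += 1
            continue
        mism = hamming(f_read[cds_off:cds_off + len(cds_ref)], cds_ref) > 0
        rows.append((rbs, sample, state, mism))
    return rows


def _collect_counts_vec(fwd, rev, fwd_mat, rev_mat, index_table, sites,
                        cds_ref, stats):
    n = rev_mat.shape[0]
    keep = np.ones(n, dtype=bool)

    anchor, _ = _best_window_vec(rev_mat, sites.constant_region,
                                 sites.max_mismatches)
    ok = anchor >= 0
    stats.no_constant_region += int(np.sum(keep & ~ok))
    keep &= ok

    # state call on the reverse mate
    p_off, _ = _best_window_vec(rev_mat, sites.attP_site, sites.max_mismatches)
    r_off, _ = _best_window_vec(rev_mat, sites.attR_site, sites.max_mismatches)
    # RBS anchor: best CDS-reference window on the forward mate (no distance
    # cap: mismatch count feeds the per-variant CDS filter)
    cds_off, cds_d = _best_window_vec(fwd_mat, cds_ref, len(cds_ref))

    rows = []
    idx = np.nonzero(keep)[0]
    rbs_len = sites.rbs_length
    for i in idx:
        a = int(anchor[i])
        r_read = rev[i]
        i1 = r_read[a + _IDX1_OFF:a] if a >= 6 else ""
        i2 = r_read[a + _IDX2_OFF:a + _IDX2_OFF + 6]
        sample = index_table.get((i1, i2))
        if sample is None:
            stats.undetermined_index += 1
            continue
        if p_off[i] >= 0:
            state = "unflipped"
        elif r_off[i] >= 0:
            state = "flipped"
        else:
            stats.unknown_state += 1
            continue
        co = int(cds_off[i])
        if co < rbs_len:
            stats.no_rbs_anchor += 1
            continue
        rbs = fwd[i][co - rbs_len:co]
        if set(rbs) - set("ACGT"):
            stats.ambiguous_rbs += 1
            continue
        rows.append((rbs, sample, state, bool(cds_d[i] > 0)))
    return rows


def _aggregate(rows, stats) -> list[VariantProfile]:
    stats.aggregated = len(rows)
    if not rows:
        return []
    df = pd.DataFrame(rows, columns=["rbs", "sample", "state", "cds_mism"])
    profiles = []
    for rbs, grp in df.groupby("rbs", sort=True):
        counts = {}
        for sample, sg in grp.groupby("sample", sort=True):
            counts[sample] = (
                int((sg.state == "unflipped").sum()),
                int((sg.state == "flipped").sum()),
            )
        profiles.append(
            VariantProfile(rbs, counts, float(grp.cds_mism.mean()))
        )
    return profiles


def profiles_to_frame(profiles: list[VariantProfile]) -> pd.DataFrame:
    """Long-format table: rbs, sample, n_unflipped, n_flipped."""
    rows = [
        (p.rbs_sequence, sample, u, f)
        for p in profiles
        for sample, (u, f) in sorted(p.counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["rbs", "sample", "n_unflipped", "n_flipped"]
    )
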