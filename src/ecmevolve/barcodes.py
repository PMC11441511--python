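"""DNA-barcode lineage tracing: raw amplicon reads to clone-dynamics metrics.

Each founder cell carries one heritable 20-bp barcode integrated from a
lentiviral library; targeted amplicon sequencing of the barcode locus reads
out clone abundances before and after selection.  The pipeline stages are:

1. merge paired-end mates into a consensus read,
2. quality-filter at mean Phred >= 30,
3. extract the 20-mer between the vector flanks with a substitution error
   tolerance of 0.1 per flank,
4. cluster sequencing-error barcodes into parent lineages (Levenshtein
   distance 1, parent/child count ratio >= 3),
5. apply the lineage-retention criteria, and
6. compute abundance, membership, log2 fold change, stiffness-preference
   and diversity-collapse summaries.
"""

from __future__ import annotations

import gzip
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FLANK5",
    "FLANK3",
    "BARCODE_LEN",
    "ReadPair",
    "MergedRead",
    "merge_read_pair",
    "quality_filter",
    "extract_barcode",
    "cluster_barcodes",
    "count_sample",
    "BarcodeCountTable",
    "apply_lineage_filters",
    "log2_fold_change",
    "preference_score",
    "diversity_summary",
    "build_lineage_table",
]

# Flanks of the 20-N barcode in the lentiviral barcoding oligo
# GAGCCTCGTCTCCCACCG-N20-GTTTTGAGACGCATGCTGCA.
FLANK5 = "GAGCCTCGTCTCCCACCG"
FLANK3 = "GTTTTGAGACGCATGCTGCA"
BARCODE_LEN = 20

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SELECTED_GROUPS = ("soft", "stiff")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    """One paired-end record; qualities are integer Phred scores per base."""

    id: str
    seq1: str
    qual1: Sequence[int]
    seq2: str
    qual2: Sequence[int]

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class MergedRead:
    id: str
    seq: str
    qual: tuple

    @property
    def mean_quality(self) -> float:
        return float(np.mean(self.qual))


def merge_read_pair(pair: ReadPair, min_overlap: int = 10,
                    max_mismatch_frac: float = 0.1) -> Optional[MergedRead]:
    """Merge mates into a consensus single read, or return None on failure.

    Mate 2 is reverse-complemented, then the longest 3'-of-mate-1 /
    5'-of-mate-2 overlap of length >= ``min_overlap`` with mismatch fraction
    <= ``max_mismatch_frac`` is taken; at disagreeing overlap positions the
    higher-quality base (and its quality) wins.
    """
    if not pair.seq1 or not pair.seq2:
        return None
    s1, q1 = pair.seq1, list(pair.qual1)
    s2 = reverse_complement(pair.seq2)
    q2 = list(pair.qual2)[::-1]

    n1, n2 = len(s1), len(s2)
    for ov in range(min(n1, n2), min_overlap - 1, -1):  # longest first
        a = s1[n1 - ov:]
        b = s2[:ov]
        mism = sum(x != y for x, y in zip(a, b))
        if mism <= max_mismatch_frac * ov:
            seq = list(s1[: n1 - ov])
            qual = q1[: n1 - ov]
            for i in range(ov):
                ia, ib = n1 - ov + i, i
                if s1[ia] == s2[ib]:
                    seq.append(s1[ia])
                    qual.append(max(q1[ia], q2[ib]))
                elif q1[ia] >= q2[ib]:
                    seq.append(s1[ia])
                    qual.append(q1[ia])
                else:
                    seq.append(s2[ib])
                    qual.append(q2[ib])
            seq.extend(s2[ov:])
            qual.extend(q2[ov:])
            return MergedRead(pair.id, "".join(seq), tuple(qual))
    return None


def quality_filter(read: MergedRead, min_mean_phred: float = 30.0,
                   min_base_phred: Optional[int] = None) -> bool:
    """Keep a consensus read iff its mean Phred is >= ``min_mean_phred``.

    ``min_base_phred`` optionally also requires every base to reach a
    per-base minimum.
    """
    if read.mean_quality < min_mean_phred:
        return False
    if min_base_phred is not None and min(read.qual) < min_base_phred:
        return False
    return True


def _find_flank(seq: str, flank: str, start: int, max_sub: int) -> int:
    """Leftmost position >= start where ``flank`` matches with <= max_sub
    substitutions (no indels); -1 if absent."""
    m = len(flank)
    for i in range(start, len(seq) - m + 1):
        mism = 0
        window = seq[i:i + m]
        for x, y in zip(window, flank):
            if x != y:
                mism += 1
                if mism > max_sub:
                    break
        if mism <= max_sub:
            return i
    return -1


def extract_barcode(seq: str, flank5: str = FLANK5, flank3: str = FLANK3,
                    error_tolerance: float = 0.1,
                    barcode_len: int = BARCODE_LEN) -> Optional[str]:
    """Extract the barcode between the vector flanks, or None.

    Each flank may differ from the read by at most
    ``floor(error_tolerance * len(flank))`` substitutions; the leftmost
    qualifying 5' anchor whose downstream 3' anchor also matches wins.
    Barcodes containing N are rejected.
    """
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty")
    max5 = math.floor(error_tolerance * len(flank5))
    max3 = math.floor(error_tolerance * len(flank3))
    pos = 0
    while True:
        i = _find_flank(seq, flank5, pos, max5)
        if i < 0:
            return None
        bc_start = i + len(flank5)
        bc_end = bc_start + barcode_len
        if bc_end + len(flank3) <= len(seq):
            window = seq[bc_end:bc_end + len(flank3)]
            mism = sum(x != y for x, y in zip(window, flank3))
            if mism <= max3:
                barcode = seq[bc_start:bc_end]
                if "N" not in barcode:
                    return barcode
        pos = i + 1


def _levenshtein_within(a: str, b: str, k: int) -> bool:
    return edlib.align(a, b, task="distance", k=k)["editDistance"] != -1


def cluster_barcodes(raw: Mapping[str, int], max_dist: int = 1,
                     min_ratio: float = 3.0) -> dict:
    """Absorb sequencing-error barcodes into parent lineages.

    Barcodes are processed in descending count order (ties lexicographic).
    Each barcode joins the cluster holding the most reads among those with
    a member within Levenshtein distance <= ``max_dist`` and a running
    cluster total >= ``min_ratio`` times the barcode's own count; otherwise
    it founds a new cluster under its own sequence.  Matching against
    cluster members (not only the founding centroid) lets multi-error reads
    chain through their single-error intermediates to the parent lineage,
    emulating message-passing clustering; absorption passes repeat until no
    cluster can be merged further.  Total read count is conserved.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if min_ratio < 1:
        raise ValueError("min_ratio must be >= 1")
    totals: dict[str, int] = {}      # centroid -> cluster read total
    members: dict[str, list] = {}    # centroid -> member barcodes
    parent: dict[str, str] = {}      # member barcode -> centroid

    def _best_target(bcs: Sequence[str], count: int, exclude: Optional[str]):
        best = None
        for mb, cen in parent.items():
            if cen == exclude or totals[cen] < min_ratio * count:
                continue
            if any(_levenshtein_within(bc, mb, max_dist) for bc in bcs):
                if best is None or totals[cen] > totals[best] or (
                        totals[cen] == totals[best] and cen < best):
                    best = cen
        return best

    for bc, count in sorted(raw.items(), key=lambda kv: (-kv[1], kv[0])):
        if count < 0:
            raise ValueError("counts must be non-negative")
        target = _best_target([bc], count, exclude=None)
        if target is None:
            totals[bc] = count
            members[bc] = [bc]
            parent[bc] = bc
        else:
            totals[target] += count
            members[target].append(bc)
            parent[bc] = target

    # late-founded small clusters (e.g. a double-error read processed before
    # its single-error intermediate) may now have an absorption path
    changed = True
    while changed:
        changed = False
        for cen in sorted(totals, key=lambda b: (totals[b], b)):
            target = _best_target(members[cen], totals[cen], exclude=cen)
            if target is not None:
                totals[target] += totals[cen]
                for mb in members[cen]:
                    parent[mb] = target
                members[target].extend(members[cen])
                del totals[cen], members[cen]
                changed = True
    return totals


# ---------------------------------------------------------------------------
# FASTQ -> per-sample counts


def _open_maybe_gzip(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_read_pairs(fastq1, fastq2) -> Iterable[ReadPair]:
    """Stream paired FASTQ files (optionally gzipped) as ReadPair records."""
    with _open_maybe_gzip(fastq1) as h1, _open_maybe_gzip(fastq2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2):
            yield ReadPair(t1.split()[0], s1.upper(),
                           tuple(ord(c) - 33 for c in q1),
                           s2.upper(), tuple(ord(c) - 33 for c in q2))


def count_sample(fastq1, fastq2, *, min_overlap: int = 10,
                 max_mismatch_frac: float = 0.1, min_mean_phred: float = 30.0,
                 flank5: str = FLANK5, flank3: str = FLANK3,
                 error_tolerance: float = 0.1, barcode_len: int = BARCODE_LEN,
                 max_dist: int = 1, min_ratio: float = 3.0):
    """Run merge -> quality filter -> extract -> cluster for one sample.

    Returns ``(clustered_counts, stats)`` where stats tracks reads lost at
    each stage.
    """
    raw: Counter = Counter()
    stats = {"pairs": 0, "merge_failed": 0, "low_quality": 0, "no_barcode": 0,
             "extracted": 0}
    for pair in iter_read_pairs(fastq1, fastq2):
        stats["pairs"] += 1
        merged = merge_read_pair(pair, min_overlap, max_mismatch_frac)
        if merged is None:
            stats["merge_failed"] += 1
            continue
        if not quality_filter(merged, min_mean_phred):
            stats["low_quality"] += 1
            continue
        bc = extract_barcode(merged.seq, flank5, flank3, error_tolerance, barcode_len)
        if bc is None:
            stats["no_barcode"] += 1
            continue
        raw[bc] += 1
        stats["extracted"] += 1
    clustered = cluster_barcodes(raw, max_dist, min_ratio)
    stats["raw_barcodes"] = len(raw)
    stats["clustered_barcodes"] = len(clustered)
    return clustered, stats


# ---------------------------------------------------------------------------
# Count table and clone-dynamics metrics


@dataclass
class BarcodeCountTable:
    """Read counts per clustered barcode lineage across samples.

    ``counts`` is a barcode x sample DataFrame of non-negative integers;
    ``groups`` maps each sample to its group (ancestral | soft | stiff).
    """

    counts: pd.DataFrame
    groups: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without a group tag: {sorted(missing)}")
        bad = set(self.groups.values()) - {"ancestral", *SELECTED_GROUPS}
        if bad:
            raise ValueError(f"unknown group tags: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.sort_index()

    @classmethod
    def from_sample_counts(cls, per_sample: Mapping[str, Mapping[str, int]],
                           groups: Mapping[str, str]) -> "BarcodeCountTable":
        df = pd.DataFrame(per_sample).fillna(0).astype(int)
        df.index.name = "barcode"
        return cls(df, dict(groups))

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list:
        return [s for s in self.samples if self.groups[s] == group]

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def frequencies(self) -> pd.DataFrame:
        """Per-sample lineage frequencies (each column sums to 1)."""
        totals = self.totals
        if (totals == 0).any():
            empty = list(totals.index[totals == 0])
            raise ValueError(f"samples with zero reads: {empty}")
        return self.counts / totals

    def to_long(self) -> pd.DataFrame:
        long = (self.counts.reset_index()
                .melt(id_vars="barcode", var_name="sample", value_name="count"))
        return long[long["count"] > 0].reset_index(drop=True)


def log2_fold_change(freq_sel: float, freq_anc: float, pseudo: float) -> float:
    """log2((freq_sel + pseudo) / (freq_anc + pseudo))."""
    if pseudo <= 0:
        raise ValueError("pseudocount must be positive")
    return math.log2((freq_sel + pseudo) / (freq_anc + pseudo))


def _default_pseudo(table: BarcodeCountTable) -> float:
    # one read in the shallowest library
    return 1.0 / float(table.totals.min())


def preference_score(soft_l2fc: Sequence[float], stiff_l2fc: Sequence[float]) -> float:
    """Mean soft log2FC minus mean stiff log2FC; positive = soft-preferring."""
    if len(soft_l2fc) == 0 or len(stiff_l2fc) == 0:
        raise ValueError("need >= 1 replicate per group")
    return float(np.mean(soft_l2fc) - np.mean(stiff_l2fc))


def apply_lineage_filters(table: BarcodeCountTable, *,
                          min_freq_anc_rule: float = 0.001,
                          max_single_group_samples: int = 2,
                          min_freq_gel_rule: float = 0.005,
                          min_count: int = 1) -> pd.DataFrame:
    """Evaluate the three lineage-retention criteria per barcode.

    A lineage is retained iff it satisfies at least one of
    rule 1 — frequency > 0.1% in some sample AND detected in an ancestral
    sample; rule 2 — detected in both selected groups, or in more than two
    samples of a single selected group; rule 3 — frequency > 0.5% in at
    least one gel-selected sample.

    Returns a DataFrame indexed by barcode with boolean columns
    ``rule1, rule2, rule3, retained``.
    """
    anc = table.samples_in_group("ancestral")
    if not anc:
        raise ValueError("table must contain an ancestral sample")
    for g in SELECTED_GROUPS:
        if not table.samples_in_group(g):
            raise ValueError(f"table must contain >= 1 {g} sample")
    freq = table.frequencies()
    detected = table.counts >= min_count

    in_anc = detected[anc].any(axis=1)
    rule1 = (freq > min_freq_anc_rule).any(axis=1) & in_anc

    soft = table.samples_in_group("soft")
    stiff = table.samples_in_group("stiff")
    in_soft = detected[soft].any(axis=1)
    in_stiff = detected[stiff].any(axis=1)
    n_soft = detected[soft].sum(axis=1)
    n_stiff = detected[stiff].sum(axis=1)
    rule2 = (in_soft & in_stiff) | (n_soft > max_single_group_samples) | \
            (n_stiff > max_single_group_samples)

    gel = soft + stiff
    rule3 = (freq[gel] > min_freq_gel_rule).any(axis=1)

    out = pd.DataFrame({"rule1": rule1, "rule2": rule2, "rule3": rule3})
    out["retained"] = out.any(axis=1)
    return out


def diversity_summary(table: BarcodeCountTable, min_count: int = 1) -> dict:
    """Unique detected lineages per sample and per group, and the percent
    decrease of the selected union relative to the ancestral count."""
    detected = table.counts >= min_count
    per_sample = detected.sum(axis=0).to_dict()
    anc = table.samples_in_group("ancestral")
    if not anc:
        raise ValueError("table must contain an ancestral sample")
    anc_count = int(detected[anc].any(axis=1).sum())
    if anc_count == 0:
        raise ValueError("no lineages detected in the ancestral sample")

    per_group, pct_decrease = {}, {}
    selected_samples = []
    for g in SELECTED_GROUPS:
        samples = table.samples_in_group(g)
        selected_samples += samples
        if samples:
            union = int(detected[samples].any(axis=1).sum())
            per_group[g] = union
            pct_decrease[g] = 100.0 * (1.0 - union / anc_count)
    union_all = int(detected[selected_samples].any(axis=1).sum()) if selected_samples else 0
    return {
        "per_sample": {k: int(v) for k, v in per_sample.items()},
        "ancestral": anc_count,
        "per_group_union": per_group,
        "selected_union": union_all,
        "percent_decrease_by_group": pct_decrease,
        "percent_decrease": 100.0 * (1.0 - union_all / anc_count),
    }


def build_lineage_table(table: BarcodeCountTable,
                        pseudo: Optional[float] = None) -> pd.DataFrame:
    """Per-lineage record: percent abundances, membership, mean log2 fold
    changes vs ancestral, soft-vs-stiff preference score, retention flags."""
    if pseudo is None:
        pseudo = _default_pseudo(table)
    freq = table.frequencies()
    anc = table.samples_in_group("ancestral")
    freq_anc = freq[anc].mean(axis=1)

    out = pd.DataFrame(index=table.counts.index)
    for s in table.samples:
        out[f"pct_{s}"] = 100.0 * freq[s]
    detected = table.counts >= 1
    out["n_samples_detected"] = detected.sum(axis=1)

    l2fc = {}
    for g in SELECTED_GROUPS:
        cols = []
        for s in table.samples_in_group(g):
            cols.append(np.log2((freq[s] + pseudo) / (freq_anc + pseudo)))
        l2fc[g] = pd.concat(cols, axis=1)
        out[f"log2fc_{g}"] = l2fc[g].mean(axis=1)
    out["preference_score"] = out["log2fc_soft"] - out["log2fc_stiff"]

    rules = apply_lineage_filters(table)
    out = out.join(rules)
    out.index.name = "barcode"
    return out


def display_barcode(barcode: str, width: int = 8) -> str:
    """Truncated display form, e.g. 'TTTCTTCA...' (stored data stays full-length)."""
    return barcode if len(barcode) <= width else barcode[:width] + "..."
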