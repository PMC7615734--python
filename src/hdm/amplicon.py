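"""UMI bisulfite-amplicon methylation calling.

Targeted bisulfite PCR libraries carry 4-bp unique molecular
identifiers (UMIs) at both ends of each amplicon so that PCR duplicates
can be collapsed. The caller runs:

1. poly-G artifact filtering — one-/two-color Illumina chemistries
   emit spurious high-confidence G runs when signal is absent; a pair
   is removed when either read has a G fraction >= 90%;
2. UMI extraction — the first 4 bases of each read are moved off the
   sequence;
3. deduplication by exact (umi1, umi2, alignment key) identity — the
   "unique" method: no UMI error-correction or clustering;
4. per-fragment methylation — calls from the two reads are merged by
   CpG position (a CpG covered by both counted once; on conflict read1
   wins and the conflict is logged), giving n_r called CpGs and m_r
   methylated calls per fragment, mean m_r/n_r; the locus-level
   aggregate is the unweighted mean of fragment means (a
   coverage-weighted mode is available).

Alignment is upstream: callers supply either raw FASTQ pairs (through
steps 1-2) or aligned per-read call strings over {Z = methylated,
z = unmethylated, . = no call}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ReadPair",
    "UmiFragment",
    "FragmentMeth",
    "polyg_filter",
    "extract_umis",
    "dedup_fragments",
    "fragment_methylation",
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_call_strings",
]

POLYG_THRESHOLD = 0.90
UMI_LEN = 4
_ALPHABET = set("ACGTN")


@dataclass
class ReadPair:
    """One paired-end read: sequences + qualities + pair id."""

    pair_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self):
        for seq in (self.seq1, self.seq2):
            if not seq or not set(seq) <= _ALPHABET:
                raise ValueError(f"invalid sequence in pair {self.pair_id!r}")
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch in {self.pair_id!r}")


@dataclass
class UmiFragment:
    """A sequenced fragment: UMIs, alignment key and per-CpG calls.

    ``calls1``/``calls2`` map CpG position -> call ("Z" methylated,
    "z" unmethylated) for read 1 and read 2.
    """

    fragment_id: str
    umi1: str
    umi2: str
    key: str  # amplicon id or chrom:start-end
    calls1: dict[int, str] = field(default_factory=dict)
    calls2: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.umi1) != UMI_LEN or len(self.umi2) != UMI_LEN:
            raise ValueError("UMIs must be exactly 4 bp")


@dataclass
class FragmentMeth:
    fragment_id: str
    n_r: int  # called CpGs in the fragment
    m_r: int  # methylated calls

    @property
    def mean(self) -> float:
        if self.n_r == 0:
            raise ValueError("mean undefined for fragment with no calls")
        return self.m_r / self.n_r


def g_fraction(seq: str) -> float:
    return seq.count("G") / len(seq)


def polyg_filter(
    pairs: list[ReadPair], threshold: float = POLYG_THRESHOLD
) -> tuple[list[ReadPair], int]:
    """Remove pairs where one or both reads are >= threshold guanine.

    The threshold is inclusive ("at least 90%"): a read at exactly the
    threshold triggers removal. Returns (kept pairs, removed count).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    kept = [
        p
        for p in pairs
        if g_fraction(p.seq1) < threshold and g_fraction(p.seq2) < threshold
    ]
    return kept, len(pairs) - len(kept)


def extract_umis(pair: ReadPair, umi_len: int = UMI_LEN) -> tuple[ReadPair, str, str]:
    """Take the first ``umi_len`` bases of each read as UMIs.

    UMIs sit at the 5' end of each read (one per side of the amplicon);
    sequences and qualities are trimmed accordingly.
    """
    if umi_len == 0:
        return pair, "", ""
    if len(pair.seq1) <= umi_len or len(pair.seq2) <= umi_len:
        raise ValueError(f"reads of pair {pair.pair_id!r} are not longer than the UMI")
    umi1, umi2 = pair.seq1[:umi_len], pair.seq2[:umi_len]
    trimmed = ReadPair(
        pair_id=pair.pair_id,
        seq1=pair.seq1[umi_len:],
        qual1=pair.qual1[umi_len:],
        seq2=pair.seq2[umi_len:],
        qual2=pair.qual2[umi_len:],
    )
    return trimmed, umi1, umi2


def dedup_fragments(fragments: list[UmiFragment]) -> tuple[list[UmiFragment], int]:
    """Collapse fragments sharing (umi1, umi2, alignment key).

    The "unique" method: exact identity only, no UMI clustering; the
    first fragment in input order represents each group. Returns
    (unique fragments, duplicates removed).
    """
    seen: dict[tuple[str, str, str], UmiFragment] = {}
    for f in fragments:
        seen.setdefault((f.umi1, f.umi2, f.key), f)
    return list(seen.values()), len(fragments) - len(seen)


def fragment_methylation(
    fragments: list[UmiFragment],
    weight_by_coverage: bool = False,
) -> tuple[list[FragmentMeth], float, int]:
    """Per-fragment methylation m_r/n_r and the locus aggregate.

    Calls from the two reads are merged by CpG position; a CpG covered
    by both reads is counted once, with read 1 winning on conflicting
    calls (conflicts are counted and returned). Fragments with no
    calls are excluded from the aggregate. The aggregate is the
    unweighted mean of fragment means, or the call-weighted mean
    (sum m_r / sum n_r) when ``weight_by_coverage``.

    Returns (per-fragment results, aggregate fraction, conflict count).
    """
    results = []
    conflicts = 0
    for f in fragments:
        merged = dict(f.calls2)
        for pos, call in f.calls1.items():
            if pos in merged and merged[pos] != call:
                conflicts += 1
            merged[pos] = call  # read1 wins
        n_r = len(merged)
        m_r = sum(1 for c in merged.values() if c == "Z")
        results.append(FragmentMeth(f.fragment_id, n_r, m_r))
    informative = [r for r in results if r.n_r > 0]
    if len(informative) < len(results):
        warnings.warn(
            f"{len(results) - len(informative)} fragment(s) with no CpG calls excluded",
            stacklevel=2,
        )
    if not informative:
        raise ValueError("no fragments with CpG calls")
    if weight_by_coverage:
        aggregate = sum(r.m_r for r in informative) / sum(r.n_r for r in informative)
    else:
        aggregate = float(np.mean([r.mean for r in informative]))
    return results, aggregate, conflicts


# ---------------------------------------------------------------------------
# I/O


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    """Read paired FASTQ files into ReadPair records."""

    def _read(path):
        records = []
        with open(path) as fh:
            while True:
                header = fh.readline().rstrip("\n")
                if not header:
                    break
                seq = fh.readline().rstrip("\n")
                fh.readline()  # separator
                qual = fh.readline().rstrip("\n")
                records.append((header[1:].split()[0], seq, qual))
        return records

    reads1, reads2 = _read(r1_path), _read(r2_path)
    if len(reads1) != len(reads2):
        raise ValueError("R1 and R2 have different read counts")
    pairs = []
    for (id1, s1, q1), (id2, s2, q2) in zip(reads1, reads2):
        if id1 != id2:
            raise ValueError(f"read id mismatch: {id1!r} vs {id2!r}")
        pairs.append(ReadPair(id1, s1, q1, s2, q2))
    return pairs


def write_fastq_pairs(pairs: list[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.pair_id}\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.pair_id}\n{p.seq2}\n+\n{p.qual2}\n")


def read_call_strings(path: str | Path) -> list[UmiFragment]:
    """Read aligned call-string TSV.

    Columns: fragment_id, umi1, umi2, key, calls1, calls2 — each call
    string is over {Z, z, .} per CpG position of the amplicon.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    fragments = []
    for row in df.itertuples(index=False):
        fragments.append(
            UmiFragment(
                fragment_id=row.fragment_id,
                umi1=row.umi1,
                umi2=row.umi2,
                key=row.key,
                calls1=_parse_calls(row.calls1),
                calls2=_parse_calls(row.calls2),
            )
        )
    return fragments


def _parse_calls(s: str) -> dict[int, str]:
    return {i: c for i, c in enumerate(s) if c in ("Z", "z")}


def write_call_strings(fragments: list[UmiFragment], path: str | Path, n_cpgs: int) -> None:
    rows = []
    for f in fragments:
        rows.append(
            {
                "fragment_id": f.fragment_id,
                "umi1": f.umi1,
                "umi2": f.umi2,
                "key": f.key,
                "calls1": _format_calls(f.calls1, n_cpgs),
                "calls2": _format_calls(f.calls2, n_cpgs),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _format_calls(calls: dict[int, str], n: int) -> str:
    return "".join(calls.get(i, ".") for i in range(n))
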