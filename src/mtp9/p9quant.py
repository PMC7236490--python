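"""Quality-filtered allele counting at p9 sites and methylation inference.

Consumes samtools-mpileup 6-column text (chrom, pos, ref, depth, bases,
quals), counts A/C/G/T per strand after a Phred base-quality filter, and
infers per-sample methylation as the alternative-allele frequency (AAF)

    aaf = 1 - ref_count / depth_kept

at each of the 11 p9 sites. Sites with depth below ``min_depth`` are
reported missing (NaN), never as zero.

The pileup base-string grammar handled here:

========  =======================================================
token     meaning
========  =======================================================
``.``     reference base, forward strand
``,``     reference base, reverse strand
ACGTN     alternative base (N excluded), forward strand
acgtn     alternative base (n excluded), reverse strand
``^X``    read start; X encodes mapping quality and is not a base
``$``     read end marker (no base)
``+n``/``-n``  insertion/deletion of n bases follows; skipped
``*``     deleted base placeholder; consumes a quality char
``>``/``<``    reference skip (spliced); consumes a quality char
========  =======================================================

Deletions, reference skips and N calls are excluded from both numerator
and denominator of the AAF (substitution-only inference); the
``count_deletions_in_depth`` flag can put ``*`` back into the denominator.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

from .sites import P9Site, P9_POSITIONS

PHRED_OFFSET = 33
BASES = ("A", "C", "G", "T")


class PileupParseError(ValueError):
    """Malformed pileup line (grammar/quality length mismatch)."""


@dataclass
class SiteAlleleCounts:
    """Quality-filtered base calls at one site for one sample."""

    sample_id: str
    position: int
    counts: dict[str, int]
    fwd_counts: dict[str, int]
    rev_counts: dict[str, int]
    depth_kept: int
    depth_raw: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.depth_kept and "no_coverage" not in self.flags:
            # depth_kept may exceed base-call sum only when deletions are
            # counted in depth; that path sets depth_kept explicitly.
            pass
        for b in BASES:
            f = self.fwd_counts.get(b, 0)
            r = self.rev_counts.get(b, 0)
            if f + r != self.counts.get(b, 0):
                raise ValueError(f"strand counts for {b} do not sum to total")


@dataclass
class MethylationProfile:
    """Per-sample inferred methylation (AAF) across the p9 sites."""

    sample_id: str
    aaf: dict[int, float] = field(default_factory=dict)       # NaN when missing
    depth_kept: dict[int, int] = field(default_factory=dict)
    qc_flags: dict[int, tuple[str, ...]] = field(default_factory=dict)


def _parse_base_string(bases: str, quals: str, lineno: int) -> list[tuple[str, bool, int]]:
    """Tokenize an mpileup base string into (base, is_forward, phred) calls.

    ``base`` is one of A/C/G/T/N/*/> after normalisation to upper case;
    indel sequences, read start/end marks are consumed and dropped. Raises
    :class:`PileupParseError` when the number of quality-consuming tokens
    does not match the quality string length.
    """
    calls: list[tuple[str, bool, int]] = []
    i = 0
    qi = 0
    nq = len(quals)
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # skip the mapping-quality char
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"line {lineno}: bare '{c}' without indel length")
            length = int(bases[i + 1 : j])
            i = j + length
            continue
        # every remaining token consumes one quality character
        if qi >= nq:
            raise PileupParseError(
                f"line {lineno}: base string has more calls than quality string"
            )
        phred = ord(quals[qi]) - PHRED_OFFSET
        qi += 1
        if c == ".":
            calls.append(("REF", True, phred))
        elif c == ",":
            calls.append(("REF", False, phred))
        elif c in "ACGTN":
            calls.append((c, True, phred))
        elif c in "acgtn":
            calls.append((c.upper(), False, phred))
        elif c == "*":
            calls.append(("*", True, phred))
        elif c in "><":
            calls.append((">", c == ">", phred))
        else:
            raise PileupParseError(f"line {lineno}: unexpected character {c!r} in base string")
        i += 1
    if qi != nq:
        raise PileupParseError(
            f"line {lineno}: {qi} base calls but {nq} quality characters"
        )
    return calls


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def parse_pileup(
    stream: TextIO | str | Path,
    sites: Sequence[P9Site],
    min_baseq: int = 20,
    sample_id: str = "",
    count_deletions_in_depth: bool = False,
) -> list[SiteAlleleCounts]:
    """Count quality-filtered alleles at ``sites`` from one sample's pileup.

    Bases with Phred < ``min_baseq`` are excluded. A site absent from the
    pileup yields a zero-depth record flagged ``no_coverage``. Returns one
    :class:`SiteAlleleCounts` per site, in site order.
    """
    close = False
    if isinstance(stream, (str, Path)):
        stream = _open_text(stream)
        close = True
    wanted = {s.position: s for s in sites}
    out: dict[int, SiteAlleleCounts] = {}
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                cols = line.split()
            if len(cols) < 6:
                raise PileupParseError(
                    f"line {lineno}: expected 6 pileup columns, got {len(cols)}"
                )
            _, pos_s, _, depth_s, bases, quals = cols[:6]
            pos = int(pos_s)
            if pos not in wanted:
                continue
            calls = _parse_base_string(bases, quals, lineno)
            fwd = {b: 0 for b in BASES}
            rev = {b: 0 for b in BASES}
            n_del_kept = 0
            ref_base = wanted[pos].ref_base
            for base, is_fwd, phred in calls:
                if phred < min_baseq:
                    continue
                if base == "REF":
                    base = ref_base
                if base == "*":
                    n_del_kept += 1
                    continue
                if base in ("N", ">"):
                    continue
                (fwd if is_fwd else rev)[base] += 1
            counts = {b: fwd[b] + rev[b] for b in BASES}
            depth_kept = sum(counts.values())
            if count_deletions_in_depth:
                depth_kept += n_del_kept
            out[pos] = SiteAlleleCounts(
                sample_id=sample_id,
                position=pos,
                counts=counts,
                fwd_counts=fwd,
                rev_counts=rev,
                depth_kept=depth_kept,
                depth_raw=int(depth_s),
            )
    finally:
        if close:
            stream.close()
    result = []
    for s in sites:
        if s.position in out:
            result.append(out[s.position])
        else:
            zero = {b: 0 for b in BASES}
            result.append(
                SiteAlleleCounts(
                    sample_id=sample_id,
                    position=s.position,
                    counts=dict(zero),
                    fwd_counts=dict(zero),
                    rev_counts=dict(zero),
                    depth_kept=0,
                    depth_raw=0,
                    flags=("no_coverage",),
                )
            )
    return result


def infer_methylation(
    counts_per_sample: Iterable[SiteAlleleCounts],
    sites: Sequence[P9Site],
    min_depth: int = 10,
) -> MethylationProfile:
    """Infer per-site methylation as AAF = 1 - ref_count/depth_kept.

    Sites with ``depth_kept`` < ``min_depth`` are set missing (NaN) and
    flagged ``low_depth`` (or ``no_coverage`` at zero depth).
    """
    by_pos = {c.position: c for c in counts_per_sample}
    sample_id = next(iter(by_pos.values())).sample_id if by_pos else ""
    prof = MethylationProfile(sample_id=sample_id)
    for s in sites:
        if s.ref_base not in BASES:
            raise ValueError(f"unknown reference base {s.ref_base!r} at {s.position}")
        c = by_pos.get(s.position)
        if c is None:
            prof.aaf[s.position] = float("nan")
            prof.depth_kept[s.position] = 0
            prof.qc_flags[s.position] = ("no_coverage",)
            continue
        flags = list(c.flags)
        base_total = sum(c.counts.values())
        if c.depth_kept < min_depth or base_total == 0:
            if c.depth_kept == 0 and "no_coverage" not in flags:
                flags.append("no_coverage")
            elif c.depth_kept > 0:
                flags.append("low_depth")
            prof.aaf[s.position] = float("nan")
        else:
            # denominator is depth_kept (may include deletions if configured)
            prof.aaf[s.position] = 1.0 - c.counts[s.ref_base] / c.depth_kept
        prof.depth_kept[s.position] = c.depth_kept
        prof.qc_flags[s.position] = tuple(flags)
    return prof


def profile_matrix(
    profiles: Sequence[MethylationProfile],
    positions: Sequence[int] = P9_POSITIONS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble profiles into a sample x site AAF matrix plus a long table.

    Column order is the p9 positions ascending; missing cells stay NaN.
    Duplicate sample ids are rejected.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id(s): {', '.join(dup)}")
    positions = sorted(positions)
    wide = pd.DataFrame(
        [[p.aaf.get(pos, float("nan")) for pos in positions] for p in profiles],
        index=pd.Index(ids, name="sample"),
        columns=positions,
    )
    rows = []
    for p in profiles:
        for pos in positions:
            rows.append(
                (
                    p.sample_id,
                    pos,
                    p.aaf.get(pos, float("nan")),
                    p.depth_kept.get(pos, 0),
                    ";".join(p.qc_flags.get(pos, ())),
                )
            )
    long = pd.DataFrame(rows, columns=["sample", "position", "aaf", "depth_kept", "flags"])
    return wide, long


def write_profile_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format="%.10g")


def read_profile_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [int(c) for c in df.columns]
    df.index.name = "sample"
    return df


def quantify_directory(
    pileup_dir: str | Path,
    sites: Sequence[P9Site],
    min_baseq: int = 20,
    min_depth: int = 10,
    pattern: str = "*.pileup",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run parse + infer over every per-sample pileup file in a directory.

    The sample id is the file stem. Returns (wide matrix, long table).
    """
    paths = sorted(Path(pileup_dir).glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no pileup files matching {pattern!r} in {pileup_dir}")
    profiles = []
    for path in paths:
        counts = parse_pileup(path, sites, min_baseq=min_baseq, sample_id=path.stem)
        profiles.append(infer_methylation(counts, sites, min_depth=min_depth))
    return profile_matrix(profiles, [s.position for s in sites])
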