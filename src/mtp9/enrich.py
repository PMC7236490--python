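"""Overrepresentation analysis of a query gene set against GMT term sets.

Classic Fisher's-exact enrichment: for each term a 2x2 table of query
membership versus term membership over a background universe, the exact
hypergeometric p-value (two-sided by the point-probability rule, or
one-sided "greater" since overrepresentation is directional), BH-FDR
across terms, and fold enrichment

    fold = observed / expected,  expected = |query| * |term| / |background|

with the conventional screen keeping fold > 2 at q < 0.05.

The background defaults to the genes actually tested upstream (the
correlation screen), not the whole genome, to avoid inflation from genes
that never could have entered the query.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import warnings

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class TermSet:
    """One annotation term: id, free-text name and its member genes."""

    term_id: str
    name: str
    members: frozenset[str]
    category: str = ""


def load_gmt(stream: TextIO | str | Path) -> list[TermSet]:
    """Parse a GMT file: tab-separated term, description, members...

    Duplicate members within a line are deduplicated with a warning; a
    line with fewer than three fields (no members) is an error naming the
    line number.
    """
    close = False
    if isinstance(stream, (str, Path)):
        stream = open(stream)
        close = True
    terms = []
    try:
        for lineno, line in enumerate(stream, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected term, description and >= 1 member"
                )
            term_id, name, *members = fields
            members = [m for m in members if m]
            if len(set(members)) != len(members):
                warnings.warn(f"GMT line {lineno} ({term_id}): duplicate members collapsed")
            if not members:
                raise ValueError(f"GMT line {lineno}: empty member list")
            terms.append(TermSet(term_id, name, frozenset(members)))
    finally:
        if close:
            stream.close()
    return terms


def overrepresentation(
    query: Iterable[str],
    term_sets: Sequence[TermSet],
    background: Iterable[str],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher's exact overrepresentation of ``query`` in each term.

    ``query`` must be a subset of ``background``. Terms with no background
    members are skipped. Returns a frame indexed by term id with observed,
    expected, fold, p and BH q, sorted by p.
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise ValueError(
            f"{len(stray)} query gene(s) absent from the background, e.g. {sorted(stray)[:3]}"
        )
    n_bg = len(background)
    n_q = len(query)
    rows = []
    for ts in term_sets:
        term = ts.members & background
        if not term:
            continue
        k = len(query & term)
        table = [
            [k, n_q - k],
            [len(term) - k, n_bg - n_q - len(term) + k],
        ]
        _, p = stats.fisher_exact(table, alternative=alternative)
        expected = n_q * len(term) / n_bg
        rows.append(
            (ts.term_id, ts.name, ts.category, k, expected,
             k / expected if expected > 0 else float("nan"), float(p))
        )
    out = pd.DataFrame(
        rows,
        columns=["term", "name", "category", "observed", "expected", "fold", "p"],
    ).set_index("term")
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out = out.sort_values("p", kind="mergesort")
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def filter_fold(
    rows: pd.DataFrame, min_fold: float = 2.0, max_q: float = 0.05
) -> pd.DataFrame:
    """Keep terms with fold strictly above ``min_fold`` and q below
    ``max_q``; sorted by fold descending."""
    if rows.empty:
        return rows
    kept = rows[(rows["fold"] > min_fold) & (rows["q"] < max_q)]
    return kept.sort_values("fold", ascending=False, kind="mergesort")
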