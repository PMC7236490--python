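"""The eleven mitochondrial tRNA position-9 (p9) sites.

Methylation (m1A/m1G) at the ninth position of several mitochondrial tRNAs
blocks reverse transcriptase during cDNA synthesis, which misincorporates
nucleotides at the modified template position. In RNA-seq pileups this shows
up as apparent multi-allelic calls, and the alternative-allele frequency
(AAF) against the mitochondrial reference is the standard proxy for the
degree of methylation. Coordinates are 1-based on an rCRS-like 16,569 bp
mitochondrial reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: 1-based rCRS coordinates of the 11 p9 sites, ascending.
P9_POSITIONS: tuple[int, ...] = (
    585, 1610, 4271, 5520, 7526, 8303, 9999, 10413, 12146, 12274, 14734,
)

#: Host tRNA of each p9 site (free-text labels).
P9_TRNA: dict[int, str] = {
    585: "mt-tRNA-Phe",
    1610: "mt-tRNA-Val",
    4271: "mt-tRNA-Ile",
    5520: "mt-tRNA-Trp",
    7526: "mt-tRNA-Asp",
    8303: "mt-tRNA-Lys",
    9999: "mt-tRNA-Gly",
    10413: "mt-tRNA-Arg",
    12146: "mt-tRNA-His",
    12274: "mt-tRNA-Ser2",
    14734: "mt-tRNA-Glu",
}

VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class P9Site:
    """One p9 site: 1-based position, reference base and a host-tRNA label."""

    position: int
    ref_base: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_base not in VALID_BASES:
            raise ValueError(f"ref_base must be one of A/C/G/T, got {self.ref_base!r}")


def sites_from_reference(
    sequence: str, positions: Sequence[int] = P9_POSITIONS
) -> list[P9Site]:
    """Build the p9 site table by reading reference bases at ``positions``.

    ``sequence`` is the full mitochondrial reference (1-based coordinates,
    so position p reads ``sequence[p - 1]``).
    """
    n = len(sequence)
    sites = []
    for pos in positions:
        if pos > n:
            raise ValueError(
                f"position {pos} exceeds reference length {n}"
            )
        sites.append(P9Site(pos, sequence[pos - 1].upper(), P9_TRNA.get(pos, "")))
    return sites


def site_table(sites: Iterable[P9Site]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.position, s.ref_base, s.label) for s in sites],
        columns=["position", "ref_base", "label"],
    )


def write_site_table(sites: Iterable[P9Site], path: str | Path) -> None:
    site_table(sites).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> list[P9Site]:
    df = pd.read_csv(path, sep="\t", dtype={"position": int})
    return [
        P9Site(int(r.position), str(r.ref_base), "" if pd.isna(r.label) else str(r.label))
        for r in df.itertuples()
    ]
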