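"""Dmrt1 polymorphism panel and haplotype matching.

Sequencing the Dmrt1 region around the second causal locus reveals 11
polymorphic sites — 9 SNPs and 2 indels across exon 2, intron 2 and
intron 3 — whose alleles segregate as exactly two haplotypes.  Haplotype 1
carries the unfavorable A at 8,564,889 (the reversal-associated allele);
haplotype 2 carries G.  Indel alleles are literal inserted strings, with
``"/"`` denoting absence; comparison is exact string match.

Positions decrease through the gene because Dmrt1 runs opposite to the
genomic coordinate order; the panel is stored as printed and sorted by
position only for lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

HAP1 = "hap1"
HAP2 = "hap2"
RECOMBINANT = "recombinant"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class PanelSite:
    position_bp: int
    region: str  # "Exon 2" | "Intron 2" | "Intron 3"
    hap1: str
    hap2: str

    def __post_init__(self) -> None:
        if self.hap1 == self.hap2:
            raise ValueError(f"site {self.position_bp}: haplotype alleles equal")


@dataclass
class PolymorphismPanel:
    sites: list[PanelSite]
    _by_pos: dict[int, PanelSite] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        positions = [s.position_bp for s in self.sites]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate site positions in panel")
        self._by_pos = {s.position_bp: s for s in self.sites}

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self) -> list[int]:
        return sorted(self._by_pos)

    def site(self, position_bp: int) -> PanelSite:
        return self._by_pos[position_bp]

    def haplotype_alleles(self, which: str) -> dict[int, str]:
        attr = {HAP1: "hap1", HAP2: "hap2"}[which]
        return {s.position_bp: getattr(s, attr) for s in self.sites}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"position_bp": s.position_bp, "region": s.region,
                 "hap1": s.hap1, "hap2": s.hap2}
                for s in self.sites
            ]
        )


def default_panel() -> PolymorphismPanel:
    """The 11-site Dmrt1 panel (9 SNPs + 2 indels), stored as printed in the
    haplotype characterization (gene orientation runs against position)."""
    rows = [
        ("A", "C", "Exon 2", 8_566_940),
        ("T", "C", "Exon 2", 8_566_916),
        ("G", "T", "Intron 2", 8_565_228),
        ("ACTAAAA", "/", "Intron 2", 8_565_219),
        ("A", "G", "Intron 2", 8_565_217),
        ("C", "G", "Intron 2", 8_565_187),
        ("C", "T", "Intron 3", 8_565_031),
        ("A", "C", "Intron 3", 8_565_018),
        ("/", "T", "Intron 3", 8_565_016),
        ("T", "C", "Intron 3", 8_565_011),
        ("A", "G", "Intron 3", 8_564_889),
    ]
    return PolymorphismPanel(
        sites=[PanelSite(p, r, h1, h2) for h1, h2, r, p in rows]
    )


@dataclass
class HaplotypeMatch:
    label: str  # hap1 | hap2 | recombinant | unknown
    covered: list[int]
    discordant: dict[int, str]  # sites not matching the assigned haplotype
    unrecognized: dict[int, str]  # alleles matching neither haplotype


def match_haplotype(
    observed: dict[int, str], panel: PolymorphismPanel | None = None
) -> HaplotypeMatch:
    """Classify an observed position->allele vector against the panel.

    hap1/hap2 require every covered site to match that haplotype; a mixture
    is ``recombinant`` (discordant sites listed); any allele matching
    neither haplotype yields ``unknown``.
    """
    panel = panel or default_panel()
    covered = sorted(p for p in observed if p in panel._by_pos)
    if not covered:
        raise ValueError("observed vector covers no panel site")
    hits1: dict[int, str] = {}
    hits2: dict[int, str] = {}
    unrecognized: dict[int, str] = {}
    for p in covered:
        site = panel.site(p)
        a = str(observed[p])
        if a == site.hap1:
            hits1[p] = a
        elif a == site.hap2:
            hits2[p] = a
        else:
            unrecognized[p] = a
    if unrecognized:
        return HaplotypeMatch(UNKNOWN, covered, {}, unrecognized)
    if not hits2:
        return HaplotypeMatch(HAP1, covered, {}, {})
    if not hits1:
        return HaplotypeMatch(HAP2, covered, {}, {})
    # mixed: report the minority sites as discordant
    minority = hits2 if len(hits2) <= len(hits1) else hits1
    return HaplotypeMatch(RECOMBINANT, covered, dict(minority), {})


def count_haplotypes(
    vectors: list[dict[int, str]], panel: PolymorphismPanel | None = None
) -> int:
    """Number of distinct complete haplotype classes among the input vectors."""
    panel = panel or default_panel()
    positions = panel.positions()
    seen = set()
    for vec in vectors:
        missing = [p for p in positions if p not in vec]
        if missing:
            raise ValueError(f"vector incomplete over panel: missing {missing[:3]}")
        seen.add(tuple(str(vec[p]) for p in positions))
    return len(seen)


def g2_allele(label: str, panel: PolymorphismPanel | None = None) -> str:
    """Allele at 8,564,889 implied by a haplotype label (hap1 -> A, the
    unfavorable allele; hap2 -> G)."""
    panel = panel or default_panel()
    site = panel.site(8_564_889)
    return {HAP1: site.hap1, HAP2: site.hap2}[label]


class HaplotypeMatcher(BaseEstimator):
    """Estimator facade over :func:`match_haplotype` for batch use."""

    def __init__(self, panel: PolymorphismPanel | None = None):
        self.panel = panel

    def fit(self, X=None, y=None):
        self.panel_ = self.panel or default_panel()
        return self

    def predict(self, X: list[dict[int, str]]) -> np.ndarray:
        if not hasattr(self, "panel_"):
            self.fit()
        return np.array([match_haplotype(v, self.panel_).label for v in X])
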