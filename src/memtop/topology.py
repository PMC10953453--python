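"""Transmembrane topology annotation and per-domain fragmentation maps.

A topology is an ordered, non-overlapping partition of residues 1..L
into transmembrane helices, loops (periplasmic / cytosolic /
extracellular), and termini. A cleavage site s (the bond between
residues s and s+1) belongs to the domain containing residue s, so
boundary bonds go to the N-terminal domain. Per-domain aggregation shows
which helices fragment preferentially and where runs of consecutive
cleavages (sequence tags) localize.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MemtopError, TopologyError
from .sitestats import SiteProfile

__all__ = [
    "DOMAIN_KINDS",
    "Domain",
    "Topology",
    "read_topology",
    "write_topology_tsv",
    "domain_summary",
    "sequence_tags",
]

DOMAIN_KINDS = {
    "tm_helix",
    "loop_periplasmic",
    "loop_cytosolic",
    "loop_extracellular",
    "terminus",
}


@dataclass(frozen=True)
class Domain:
    label: str
    start: int  # 1-based inclusive
    end: int
    kind: str


@dataclass
class Topology:
    """Ordered domains jointly covering residues 1..L without overlap."""

    domains: list[Domain]

    def __post_init__(self) -> None:
        if not self.domains:
            raise TopologyError("topology needs at least one domain")
        doms = sorted(self.domains, key=lambda d: d.start)
        pos = 1
        for d in doms:
            if d.kind not in DOMAIN_KINDS:
                raise TopologyError(f"unknown domain kind {d.kind!r}")
            if d.start > d.end:
                raise TopologyError(f"domain {d.label}: start {d.start} > end {d.end}")
            if d.start < pos:
                raise TopologyError(f"domain {d.label} overlaps the previous domain")
            if d.start > pos:
                raise TopologyError(
                    f"gap in topology before {d.label} (residues {pos}..{d.start - 1})"
                )
            pos = d.end + 1
        self.domains = doms

    @property
    def length(self) -> int:
        return self.domains[-1].end

    def domain_of(self, residue: int) -> Domain:
        """The domain containing a 1-based residue index."""
        if not 1 <= residue <= self.length:
            raise MemtopError(f"residue {residue} outside 1..{self.length}")
        starts = [d.start for d in self.domains]
        idx = int(np.searchsorted(starts, residue, side="right")) - 1
        return self.domains[idx]

    def tm_labels(self) -> list[str]:
        return [d.label for d in self.domains if d.kind == "tm_helix"]


def read_topology(path: str | Path, autofill_gaps: bool = False) -> Topology:
    """Read a topology TSV with columns label, start, end, kind.

    With ``autofill_gaps`` unlabelled stretches between listed domains are
    filled as loops (``loop_autofill_<n>`` with kind terminus at the ends,
    loop_cytosolic between); otherwise a gap raises TopologyError.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"label", "start", "end", "kind"}
    if not required <= set(df.columns):
        raise TopologyError(f"topology TSV needs columns {sorted(required)}")
    domains = [
        Domain(str(r.label), int(r.start), int(r.end), str(r.kind))
        for r in df.itertuples(index=False)
    ]
    if autofill_gaps:
        domains = _fill_gaps(sorted(domains, key=lambda d: d.start))
    return Topology(domains)


def _fill_gaps(domains: list[Domain]) -> list[Domain]:
    out: list[Domain] = []
    pos = 1
    n = 0
    for d in domains:
        if d.start > pos:
            kind = "terminus" if not out else "loop_cytosolic"
            out.append(Domain(f"autofill_{n}", pos, d.start - 1, kind))
            n += 1
        out.append(d)
        pos = d.end + 1
    return out


def write_topology_tsv(topo: Topology, path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": [d.label for d in topo.domains],
            "start": [d.start for d in topo.domains],
            "end": [d.end for d in topo.domains],
            "kind": [d.kind for d in topo.domains],
        }
    ).to_csv(path, sep="\t", index=False)


def domain_summary(
    profile: SiteProfile,
    topo: Topology,
    masked_sites: set[int] | None = None,
) -> pd.DataFrame:
    """Per-domain fragmentation aggregates.

    Columns: label, kind, start, end, total_norm_intensity,
    fraction_of_total, n_sites_with_fragments, longest_tag, n_masked_sites.
    ``masked_sites`` (disulfide-infeasible sites from the theoretical
    ledger) lets absence-by-disulfide be distinguished from absence
    despite feasibility.
    """
    if topo.length != profile.sequence_length:
        raise MemtopError(
            f"topology length {topo.length} != profile length "
            f"{profile.sequence_length}"
        )
    masked = masked_sites or set()
    covered = set(profile.covered_sites.tolist())
    total_all = profile.total_norm_intensity.sum()
    rows = []
    for d in topo.domains:
        # sites s in this domain: residue s in [start, end], s <= L-1
        lo, hi = d.start, min(d.end, profile.sequence_length - 1)
        sites = range(lo, hi + 1) if lo <= hi else range(0)
        tot = float(sum(profile.total_norm_intensity[s - 1] for s in sites))
        ncov = sum(1 for s in sites if s in covered)
        longest = cur = 0
        for s in sites:
            cur = cur + 1 if s in covered else 0
            longest = max(longest, cur)
        rows.append(
            {
                "label": d.label,
                "kind": d.kind,
                "start": d.start,
                "end": d.end,
                "total_norm_intensity": tot,
                "fraction_of_total": tot / total_all if total_all > 0 else 0.0,
                "n_sites_with_fragments": ncov,
                "longest_tag": longest,
                "n_masked_sites": sum(1 for s in sites if s in masked),
            }
        )
    return pd.DataFrame(rows)


def sequence_tags(
    profile: SiteProfile, topo: Topology, min_len: int = 2
) -> list[tuple[str, int, int]]:
    """Maximal runs of >= min_len consecutive covered cleavage sites.

    Each tag is attributed to the domain holding the majority of its
    sites; ties go to the N-terminal-most such domain. Returns
    (domain label, first site, last site) tuples in sequence order.
    """
    if min_len < 2:
        raise MemtopError("min_len must be >= 2")
    covered = sorted(profile.covered_sites.tolist())
    runs: list[tuple[int, int]] = []
    start = prev = None
    for s in covered:
        if prev is None or s != prev + 1:
            if prev is not None and prev - start + 1 >= min_len:
                runs.append((start, prev))
            start = s
        prev = s
    if prev is not None and prev - start + 1 >= min_len:
        runs.append((start, prev))

    out = []
    for lo, hi in runs:
        counts: dict[str, int] = {}
        order: dict[str, int] = {}
        for s in range(lo, hi + 1):
            d = topo.domain_of(s)
            counts[d.label] = counts.get(d.label, 0) + 1
            order.setdefault(d.label, d.start)
        label = min(counts, key=lambda lbl: (-counts[lbl], order[lbl]))
        out.append((label, lo, hi))
    return out
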