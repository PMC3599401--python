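"""In-silico restriction digestion and probe-to-fragment mapping.

The DMH assay fragments genomic DNA with MseI (recognition site TTAA, cut
T^TAA) and interrogates fragments that carry at least one methylation-
sensitive site (HpaII CCGG or BstUI CGCG).  This module reproduces that
step computationally: it digests a genome, counts methylation-sensitive
sites per fragment, maps array probes to fragments by full containment,
and applies the informative-fragment filter (length 150-3,000 bp, at
least one fully contained probe, at least one HpaII/BstUI site).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

MSEI_SITE = "TTAA"
# MseI cuts T^TAA: the cut point sits 1 bp into the recognition site.
MSEI_CUT_OFFSET = 1
HPAII_SITE = "CCGG"
BSTUI_SITE = "CGCG"

#: Informative-fragment length bounds, inclusive on both ends.
MIN_FRAGMENT_LENGTH = 150
MAX_FRAGMENT_LENGTH = 3000


@dataclass(frozen=True)
class Fragment:
    """One MseI fragment (0-based half-open coordinates)."""

    id: str
    chrom: str
    start: int
    end: int
    n_hpaii: int = 0
    n_bstui: int = 0
    probe_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_sites(self) -> int:
        """Total count of methylation-sensitive sites inside the fragment."""
        return self.n_hpaii + self.n_bstui


@dataclass(frozen=True)
class Probe:
    """One array probe; ``fragment_id`` is set iff fully contained."""

    id: str
    chrom: str
    start: int
    end: int
    fragment_id: str | None = None


def find_sites(sequence: str, motif: str) -> list[int]:
    """All start positions of ``motif`` in ``sequence``, overlapping included.

    Positions are 0-based.  Matching is case-insensitive on the sequence;
    ambiguity codes (``N`` etc.) never match.

    >>> find_sites("CGCGCG", "CGCG")
    [0, 2]
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} contains non-ACGT characters")
    seq = sequence.upper()
    positions: list[int] = []
    pos = seq.find(motif)
    while pos != -1:
        positions.append(pos)
        pos = seq.find(motif, pos + 1)  # step 1 so overlapping hits count
    return positions


def _count_sites_within(positions: list[int], motif_len: int, start: int, end: int) -> int:
    """Count motif occurrences fully inside [start, end)."""
    import bisect

    lo = bisect.bisect_left(positions, start)
    hi = bisect.bisect_right(positions, end - motif_len)
    return max(0, hi - lo)


def digest_chromosome(chrom: str, sequence: str, id_prefix: str = "frag") -> list[Fragment]:
    """Digest one chromosome with MseI.

    Cuts fall after the first T of each TTAA, so internal fragments start
    with TAA and end with T; the first and last fragments take the
    chromosome ends.  Fragments tile the chromosome without gaps or
    overlaps.  Methylation-sensitive sites are counted only when the motif
    lies fully inside a fragment: a site straddling a cut is destroyed by
    the digestion and does not count.
    """
    if len(sequence) == 0:
        logger.warning("chromosome %s is empty; no fragments emitted", chrom)
        return []
    cuts = [p + MSEI_CUT_OFFSET for p in find_sites(sequence, MSEI_SITE)]
    bounds = [0] + cuts + [len(sequence)]
    hpaii = find_sites(sequence, HPAII_SITE)
    bstui = find_sites(sequence, BSTUI_SITE)
    fragments = []
    for i, (start, end) in enumerate(zip(bounds[:-1], bounds[1:])):
        fragments.append(
            Fragment(
                id=f"{id_prefix}_{chrom}_{i:05d}",
                chrom=chrom,
                start=start,
                end=end,
                n_hpaii=_count_sites_within(hpaii, len(HPAII_SITE), start, end),
                n_bstui=_count_sites_within(bstui, len(BSTUI_SITE), start, end),
            )
        )
    return fragments


def digest_genome(genome: dict[str, str]) -> list[Fragment]:
    """Digest every chromosome of ``genome`` (name -> sequence) with MseI."""
    fragments: list[Fragment] = []
    for chrom in genome:
        fragments.extend(digest_chromosome(chrom, genome[chrom]))
    return fragments


def map_probes(probes: list[Probe], fragments: list[Fragment]) -> list[Probe]:
    """Assign probes to fragments by full containment.

    A probe maps to a fragment iff its interval is fully contained in the
    fragment interval on the same chromosome; probes spanning a cut site
    stay unassigned (their target is destroyed by the digestion).  Because
    fragments tile each chromosome, containment is resolved by locating
    the fragment covering the probe start.
    """
    by_chrom: dict[str, list[Fragment]] = {}
    for frag in fragments:
        by_chrom.setdefault(frag.chrom, []).append(frag)
    starts: dict[str, list[int]] = {}
    for chrom, frs in by_chrom.items():
        frs.sort(key=lambda f: f.start)
        starts[chrom] = [f.start for f in frs]

    import bisect

    mapped = []
    for probe in probes:
        frs = by_chrom.get(probe.chrom)
        fragment_id = None
        if frs:
            i = bisect.bisect_right(starts[probe.chrom], probe.start) - 1
            if i >= 0 and frs[i].start <= probe.start and probe.end <= frs[i].end:
                fragment_id = frs[i].id
        mapped.append(replace(probe, fragment_id=fragment_id))
    n_mapped = sum(p.fragment_id is not None for p in mapped)
    if mapped:
        logger.info(
            "mapped %d of %d probes (%.1f%%) to fragments",
            n_mapped, len(mapped), 100.0 * n_mapped / len(mapped),
        )
    return mapped


def attach_probes(fragments: list[Fragment], probes: list[Probe]) -> list[Fragment]:
    """Return fragments with ``probe_ids`` filled from mapped probes."""
    per_frag: dict[str, list[str]] = {}
    for probe in probes:
        if probe.fragment_id is not None:
            per_frag.setdefault(probe.fragment_id, []).append(probe.id)
    return [
        replace(f, probe_ids=tuple(per_frag.get(f.id, ())))
        for f in fragments
    ]


def select_informative_fragments(
    fragments: list[Fragment],
    probes: list[Probe] | None = None,
    min_length: int = MIN_FRAGMENT_LENGTH,
    max_length: int = MAX_FRAGMENT_LENGTH,
) -> list[Fragment]:
    """Apply the informative-fragment filter.

    A fragment is kept iff ``min_length <= length <= max_length`` (bounds
    inclusive), it maps at least one complete probe, and it contains at
    least one HpaII or BstUI site.  If ``probes`` is given, mapping is
    performed (or refreshed) internally; otherwise ``probe_ids`` must
    already be attached.
    """
    if probes is not None:
        mapped = map_probes(probes, fragments)
        fragments = attach_probes(fragments, mapped)
    return [
        f
        for f in fragments
        if min_length <= f.length <= max_length
        and len(f.probe_ids) >= 1
        and f.n_sites >= 1
    ]


def fragments_to_frame(fragments: list[Fragment]) -> pd.DataFrame:
    """Tabulate fragments (BED-like TSV layout used across the pipeline)."""
    return pd.DataFrame(
        {
            "fragment_id": [f.id for f in fragments],
            "chrom": [f.chrom for f in fragments],
            "start": [f.start for f in fragments],
            "end": [f.end for f in fragments],
            "length": [f.length for f in fragments],
            "n_hpaii": [f.n_hpaii for f in fragments],
            "n_bstui": [f.n_bstui for f in fragments],
            "n_probes": [len(f.probe_ids) for f in fragments],
        }
    )


def probes_to_frame(probes: list[Probe]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [p.id for p in probes],
            "chrom": [p.chrom for p in probes],
            "start": [p.start for p in probes],
            "end": [p.end for p in probes],
            "fragment_id": [p.fragment_id for p in probes],
        }
    )
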