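"""Probe design for two-channel circRNA smFISH.

A circFISH experiment distinguishes the circular and linear isoforms of a
gene with two probe sets: the PC set tiles the exon(s) retained in the
circRNA (and therefore binds both isoforms), while the PL set tiles exons
present only in the linear transcript. A spot seen in both channels is a
full-length linear molecule; a PC-only spot is a circRNA.

This module partitions a spliced transcript into the two target regions and
tiles 18-20 nt antisense DNA probes along each, enforcing the standard
smFISH design rules: a GC content window (default 35-55%, inclusive) and a
minimum 2-nt gap between adjacent binding sites to avoid fluorophore
quenching. Tiling is greedy left-to-right: at each cursor position the
candidate window is emitted if it passes the GC filter (cursor then jumps
past the window plus the gap), otherwise the cursor advances by one base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TranscriptModel",
    "Probe",
    "ProbeSet",
    "partition_target_regions",
    "tile_probes",
    "max_probe_count",
    "min_target_length",
    "design_probe_sets",
    "read_transcript",
    "write_probe_fasta",
    "write_probe_tsv",
]

#: fewer probes than this gives a dim, unreliable diffraction-limited spot
MIN_RECOMMENDED_PROBES = 15

_VALID_BASES = set("ACGTU")


def _normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T, and reject non-nucleotide characters."""
    seq = seq.upper()
    for pos, base in enumerate(seq):
        if base not in _VALID_BASES:
            raise ValueError(
                f"invalid character {base!r} at position {pos} in {context}; "
                "expected A/C/G/T/U"
            )
    return seq.replace("U", "T")


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript with exon structure and the circularized exons.

    Coordinates are transcript-local, 0-based, half-open. Exons must be
    sorted, contiguous and cover the whole sequence; the circularized exons
    must form a non-empty contiguous run that is a proper subset of all
    exons (a fully-circularized transcript leaves no linear-only target).
    """

    gene_id: str
    spliced_sequence: str
    exons: tuple[tuple[int, int], ...]
    circ_exon_indices: frozenset[int]

    def __post_init__(self) -> None:
        seq = _normalize_sequence(self.spliced_sequence, context=f"transcript {self.gene_id}")
        object.__setattr__(self, "spliced_sequence", seq)
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        circ = frozenset(int(i) for i in self.circ_exon_indices)
        object.__setattr__(self, "circ_exon_indices", circ)

        if not exons:
            raise ValueError("transcript must have at least one exon")
        cursor = 0
        for i, (s, e) in enumerate(exons):
            if s != cursor or e <= s:
                raise ValueError(
                    f"exon {i} [{s}, {e}) is not contiguous with the previous "
                    f"exon end {cursor}"
                )
            cursor = e
        if cursor != len(seq):
            raise ValueError(
                f"exons cover [0, {cursor}) but the sequence has length {len(seq)}"
            )
        if not circ:
            raise ValueError("circ_exon_indices is empty: no circRNA target region")
        if not circ <= set(range(len(exons))):
            raise ValueError("circ_exon_indices out of range")
        if circ == set(range(len(exons))):
            raise ValueError(
                "no linear-only region: every exon is part of the circRNA"
            )
        run = sorted(circ)
        if run != list(range(run[0], run[-1] + 1)):
            raise ValueError("circularized exons must form a contiguous run")

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class Probe:
    """One antisense oligo: the reverse complement of its target window."""

    target_start: int
    target_end: int
    sequence: str
    gc_fraction: float
    set_label: str
    fluor: str = ""

    @property
    def length(self) -> int:
        return self.target_end - self.target_start


@dataclass
class ProbeSet:
    set_label: str
    probes: list[Probe]
    fluor: str = ""
    target_region: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        starts = [p.target_start for p in self.probes]
        if starts != sorted(starts):
            raise ValueError("probes must be sorted by target_start")

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def low_count_warning(self) -> bool:
        """True when the set is below the recommended 15-probe minimum."""
        return len(self.probes) < MIN_RECOMMENDED_PROBES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "set_label": [p.set_label for p in self.probes],
                "index": range(len(self.probes)),
                "target_start": [p.target_start for p in self.probes],
                "target_end": [p.target_end for p in self.probes],
                "sequence": [p.sequence for p in self.probes],
                "gc_fraction": [p.gc_fraction for p in self.probes],
                "fluor": [p.fluor for p in self.probes],
            }
        )


def _merge_runs(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge adjacent (touching) intervals into contiguous runs."""
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [tuple(iv) for iv in merged]


def partition_target_regions(
    transcript: TranscriptModel,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split a transcript into the PC (circularized) and PL (linear-only) regions.

    Returns ``(pc_region, pl_region)`` as lists of transcript intervals,
    with touching exons merged into contiguous runs. The two regions are
    disjoint and together cover the transcript. Because the circularized
    exons form one contiguous run, the PC region is a single interval and
    the PL region has at most two.
    """
    pc = [transcript.exons[i] for i in sorted(transcript.circ_exon_indices)]
    pl = [
        transcript.exons[i]
        for i in range(transcript.n_exons)
        if i not in transcript.circ_exon_indices
    ]
    return _merge_runs(pc), _merge_runs(pl)


def max_probe_count(L: int, probe_len: int, gap: int) -> int:
    """Closed-form capacity of the tiling: floor((L + gap) / (probe_len + gap)).

    Equals the number of probes ``tile_probes`` emits on a region of length
    ``L`` with the GC filter off. Returns 0 when the region is shorter than
    one probe.
    """
    if probe_len < 1 or gap < 0:
        raise ValueError("probe_len must be >= 1 and gap >= 0")
    if L < probe_len:
        return 0
    return (L + gap) // (probe_len + gap)


def min_target_length(n_probes: int, probe_len: int = 20, gap: int = 2) -> int:
    """Shortest target accommodating ``n_probes`` probes with the given gap."""
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    return n_probes * probe_len + (n_probes - 1) * gap


def tile_probes(
    region_sequence: str,
    probe_len: int = 20,
    min_gap: int = 2,
    gc_bounds: tuple[float, float] = (0.35, 0.55),
    gc_filter: bool = True,
    *,
    set_label: str = "PC",
    fluor: str = "",
    offset: int = 0,
) -> ProbeSet:
    """Greedily tile antisense probes along one contiguous target region.

    The cursor starts at the region's 5' end. The window of ``probe_len``
    bases is emitted as a probe when its GC fraction lies inside
    ``gc_bounds`` (inclusive) or when the filter is off, after which the
    cursor advances by ``probe_len + min_gap``; a rejected window advances
    the cursor by one base. ``offset`` shifts reported coordinates into
    transcript space. An empty result is returned (with the low-count
    warning flag set) rather than raised.
    """
    if not 18 <= probe_len <= 20:
        raise ValueError("probe_len must be within [18, 20]")
    seq = _normalize_sequence(region_sequence, context="region sequence")
    if len(seq) < probe_len:
        raise ValueError(
            f"region length {len(seq)} is shorter than probe_len {probe_len}"
        )
    lo, hi = gc_bounds
    probes: list[Probe] = []
    cursor = 0
    while cursor + probe_len <= len(seq):
        window = seq[cursor : cursor + probe_len]
        gc = (window.count("G") + window.count("C")) / probe_len
        if (not gc_filter) or lo <= gc <= hi:
            probes.append(
                Probe(
                    target_start=offset + cursor,
                    target_end=offset + cursor + probe_len,
                    sequence=str(Seq(window).reverse_complement()),
                    gc_fraction=gc,
                    set_label=set_label,
                    fluor=fluor,
                )
            )
            cursor += probe_len + min_gap
        else:
            cursor += 1
    probe_set = ProbeSet(
        set_label=set_label,
        probes=probes,
        fluor=fluor,
        target_region=[(offset, offset + len(seq))],
    )
    if probe_set.low_count_warning:
        warnings.warn(
            f"{set_label} set has {len(probes)} probes; at least "
            f"{MIN_RECOMMENDED_PROBES} are recommended for a reliable spot",
            stacklevel=2,
        )
    return probe_set


def design_probe_sets(
    transcript: TranscriptModel,
    probe_len: int = 20,
    min_gap: int = 2,
    gc_bounds: tuple[float, float] = (0.35, 0.55),
    gc_filter: bool = True,
    pl_fluor: str = "TexasRed",
    pc_fluor: str = "Cy5",
    pl_exon_indices: set[int] | None = None,
) -> tuple[ProbeSet, ProbeSet]:
    """Design the PL and PC probe sets for one transcript.

    Probes may span exon junctions inside a region (those junctions exist in
    both isoforms) but never the gap between two non-adjacent runs of the PL
    region. ``pl_exon_indices`` optionally restricts the PL region to a
    subset of the non-circularized exons, as is useful when some linear-only
    exons are too short or otherwise undesirable.

    Returns ``(pl_set, pc_set)``.
    """
    pc_region, pl_region = partition_target_regions(transcript)
    if pl_exon_indices is not None:
        extra = set(pl_exon_indices) & set(transcript.circ_exon_indices)
        if extra:
            raise ValueError(
                f"pl_exon_indices {sorted(extra)} are circularized exons"
            )
        pl_region = _merge_runs(
            [transcript.exons[i] for i in sorted(pl_exon_indices)]
        )
        if not pl_region:
            raise ValueError("pl_exon_indices selects no exons")

    def _tile_region(region, label, fluor):
        probes: list[Probe] = []
        for s, e in region:
            if e - s < probe_len:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sub = tile_probes(
                    transcript.spliced_sequence[s:e],
                    probe_len=probe_len,
                    min_gap=min_gap,
                    gc_bounds=gc_bounds,
                    gc_filter=gc_filter,
                    set_label=label,
                    fluor=fluor,
                    offset=s,
                )
            probes.extend(sub.probes)
        out = ProbeSet(label, probes, fluor=fluor, target_region=list(region))
        if out.low_count_warning:
            warnings.warn(
                f"{label} set for {transcript.gene_id} has {len(probes)} "
                f"probes; at least {MIN_RECOMMENDED_PROBES} are recommended",
                stacklevel=3,
            )
        return out

    pl_set = _tile_region(pl_region, "PL", pl_fluor)
    pc_set = _tile_region(pc_region, "PC", pc_fluor)
    return pl_set, pc_set


# ---------------------------------------------------------------------------
# file formats


def read_transcript(
    fasta_path: str | Path, exon_table_path: str | Path, gene_id: str | None = None
) -> TranscriptModel:
    """Build a TranscriptModel from a FASTA file and an exon TSV.

    The exon table has columns gene_id, exon_index, start, end, in_circle
    (0/1) with 0-based half-open transcript coordinates.
    """
    records = {rec.id: rec for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    table = pd.read_csv(exon_table_path, sep="\t")
    required = {"gene_id", "exon_index", "start", "end", "in_circle"}
    if not required <= set(table.columns):
        raise ValueError(f"exon table must have columns {sorted(required)}")
    if gene_id is None:
        gene_id = table["gene_id"].iloc[0]
    sub = table[table["gene_id"] == gene_id].sort_values("exon_index")
    if sub.empty:
        raise ValueError(f"gene {gene_id!r} not in exon table")
    if gene_id not in records:
        raise ValueError(f"gene {gene_id!r} not in FASTA {fasta_path}")
    return TranscriptModel(
        gene_id=gene_id,
        spliced_sequence=str(records[gene_id].seq),
        exons=tuple(zip(sub["start"], sub["end"])),
        circ_exon_indices=frozenset(
            sub.loc[sub["in_circle"] == 1, "exon_index"].astype(int)
        ),
    )


def write_probe_fasta(probe_sets: list[ProbeSet], gene_id: str, path: str | Path) -> None:
    """Write probes as FASTA with headers gene|set_label|index|start-end."""
    records = []
    for ps in probe_sets:
        for i, p in enumerate(ps.probes):
            records.append(
                SeqRecord(
                    Seq(p.sequence),
                    id=f"{gene_id}|{p.set_label}|{i}|{p.target_start}-{p.target_end}",
                    description="",
                )
            )
    SeqIO.write(records, str(path), "fasta")


def write_probe_tsv(probe_sets: list[ProbeSet], gene_id: str, path: str | Path) -> None:
    frames = [ps.to_frame() for ps in probe_sets]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.insert(0, "gene_id", gene_id)
    out.to_csv(path, sep="\t", index=False)
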