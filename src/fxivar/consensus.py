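"""Consensus Apple-domain mapping.

The four Apple domains are homologous ~90-residue PAN-family folds, each
carrying six conserved cysteines (C1..C6) that form the three
intradomain bridges C1-C6, C2-C5 and C3-C4. Aligning the four domain
sequences into one frame lets variants from all four project onto common
consensus columns, exposing positions that are repeatedly hit.

The alignment is *anchored*: the six Cys columns are fixed a priori
(every domain must supply a Cys at each anchor) and only the seven
inter-anchor segments are aligned, each by standard global alignment
(BLOSUM62, affine gaps, configurable) merged center-star style. This is
a sequence-level substitute for structural superposition: the anchor
columns are identical, the consensus length may differ by a few columns
depending on inter-anchor gap placement.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .aminoacids import AA3_TO_1
from .census import Effect, Phenotype, VariantRecord

__all__ = ["ConsensusMap", "align_apples", "project_variants", "default_aligner"]


def default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


@dataclass
class ConsensusMap:
    """Alignment of the four Apple domains onto consensus columns (0-based).

    ``mapping`` sends each domain's HGVS residue number to its column;
    the mappings are strictly increasing (no crossings). ``residues``
    lists, per column, the aligned ``(residue_hgvs, aa)`` of each domain
    present there. ``cys_columns`` labels the six anchored columns
    C1..C6; each contains a Cys from all four domains by construction.
    """

    n_columns: int
    mapping: dict[str, dict[int, int]]
    residues: dict[int, dict[str, tuple[int, str]]]
    cys_columns: dict[int, str] = field(default_factory=dict)

    def column_of(self, domain: str, residue_hgvs: int) -> int | None:
        return self.mapping.get(domain, {}).get(residue_hgvs)

    def to_frame(self) -> pd.DataFrame:
        """Wide per-column table: one residue column per domain + Cys label."""
        rows = []
        domains = sorted(self.mapping)
        for col in range(self.n_columns):
            row = {"column": col, "cys_index": self.cys_columns.get(col, "")}
            for d in domains:
                pos_aa = self.residues.get(col, {}).get(d)
                row[d] = f"{pos_aa[1]}{pos_aa[0]}" if pos_aa else "-"
            rows.append(row)
        return pd.DataFrame(rows)


def _pairwise_map(aligner, center: str, other: str):
    """Map ``other`` onto ``center`` coordinates.

    Returns ``(match, inserts)``: ``match[other_idx] = center_idx`` for
    aligned residues, and ``inserts[boundary]`` listing other residues
    inserted before center position ``boundary``.
    """
    match: dict[int, int] = {}
    inserts: dict[int, list[int]] = defaultdict(list)
    if not other:
        return match, inserts
    if not center:
        inserts[0] = list(range(len(other)))
        return match, inserts
    best = aligner.align(center, other)[0]
    cblocks, oblocks = best.aligned
    prev_oe = 0
    for (cs, ce), (os_, oe) in zip(cblocks, oblocks):
        for k in range(prev_oe, os_):
            inserts[cs].append(k)
        for k in range(ce - cs):
            match[os_ + k] = cs + k
        prev_oe = oe
    for k in range(prev_oe, len(other)):
        inserts[len(center)].append(k)
    return match, inserts


def _align_segment_set(segments: dict[str, str], aligner) -> tuple[int, dict[str, list[int]]]:
    """Center-star multi-alignment of one inter-anchor segment slot.

    Returns the number of columns and, per domain, the column index of
    each of its residues (in order).
    """
    if all(len(s) == 0 for s in segments.values()):
        return 0, {d: [] for d in segments}
    center_name = max(segments, key=lambda d: (len(segments[d]), d))
    center = segments[center_name]
    maps = {
        d: _pairwise_map(aligner, center, s)
        for d, s in segments.items()
        if d != center_name
    }
    n_ins = [0] * (len(center) + 1)
    for match, inserts in maps.values():
        for b, idxs in inserts.items():
            n_ins[b] = max(n_ins[b], len(idxs))
    # column of center position k and start of insert region at boundary b
    col_center = {}
    region_start = {}
    col = 0
    for b in range(len(center) + 1):
        region_start[b] = col
        col += n_ins[b]
        if b < len(center):
            col_center[b] = col
            col += 1
    n_cols = col

    positions: dict[str, list[int]] = {
        center_name: [col_center[k] for k in range(len(center))]
    }
    for d, (match, inserts) in maps.items():
        cols = [-1] * len(segments[d])
        for oi, ci in match.items():
            cols[oi] = col_center[ci]
        for b, idxs in inserts.items():
            for off, oi in enumerate(idxs):
                cols[oi] = region_start[b] + off
        positions[d] = cols
    return n_cols, positions


class AnchorError(ValueError):
    """A required anchor cysteine is absent from a sequence."""


def align_apples(
    sequences: Mapping[str, str],
    cys_anchors: Mapping[str, Sequence[int]],
    start_hgvs: Mapping[str, int] | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> ConsensusMap:
    """Anchor-constrained alignment of the Apple-domain sequences.

    Parameters
    ----------
    sequences
        Domain name -> one-letter sequence.
    cys_anchors
        Domain name -> the six conserved Cys positions, as HGVS residue
        numbers when ``start_hgvs`` is given, else 0-based indices.
    start_hgvs
        Domain name -> HGVS number of the first sequence position.

    Each sequence must carry Cys at every anchor (otherwise
    :class:`AnchorError`). Anchors are forced into shared columns; the
    inter-anchor segments are aligned by global alignment and merged.
    """
    aligner = aligner or default_aligner()
    domains = list(sequences)
    if set(cys_anchors) != set(domains):
        raise ValueError("anchor table must cover exactly the given domains")
    n_anchor = {len(cys_anchors[d]) for d in domains}
    if len(n_anchor) != 1:
        raise ValueError("all domains must have the same number of anchors")
    k_anchors = n_anchor.pop()

    idx_anchors: dict[str, list[int]] = {}
    for d in domains:
        offs = []
        for pos in cys_anchors[d]:
            i = pos - start_hgvs[d] if start_hgvs else pos
            if not (0 <= i < len(sequences[d])) or sequences[d][i] != "C":
                raise AnchorError(
                    f"{d}: anchor Cys expected at position {pos}, "
                    f"found {sequences[d][i] if 0 <= i < len(sequences[d]) else 'nothing'!r}"
                )
            offs.append(i)
        if offs != sorted(offs):
            raise ValueError(f"{d}: anchors must be in sequence order")
        idx_anchors[d] = offs

    # segment slots: before C1, between consecutive anchors, after C6
    slots: list[dict[str, str]] = []
    for s in range(k_anchors + 1):
        seg = {}
        for d in domains:
            lo = 0 if s == 0 else idx_anchors[d][s - 1] + 1
            hi = idx_anchors[d][s] if s < k_anchors else len(sequences[d])
            seg[d] = sequences[d][lo:hi]
        slots.append(seg)

    mapping: dict[str, dict[int, int]] = {d: {} for d in domains}
    residues: dict[int, dict[str, tuple[int, str]]] = defaultdict(dict)
    cys_columns: dict[int, str] = {}

    def _hgvs(d: str, idx: int) -> int:
        return idx + (start_hgvs[d] if start_hgvs else 0)

    col0 = 0
    for s in range(k_anchors + 1):
        n_cols, positions = _align_segment_set(slots[s], aligner)
        for d in domains:
            lo = 0 if s == 0 else idx_anchors[d][s - 1] + 1
            for oi, c in enumerate(positions[d]):
                idx = lo + oi
                colx = col0 + c
                mapping[d][_hgvs(d, idx)] = colx
                residues[colx][d] = (_hgvs(d, idx), sequences[d][idx])
        col0 += n_cols
        if s < k_anchors:
            cys_columns[col0] = f"C{s + 1}"
            for d in domains:
                idx = idx_anchors[d][s]
                mapping[d][_hgvs(d, idx)] = col0
                residues[col0][d] = (_hgvs(d, idx), "C")
            col0 += 1

    for d in domains:  # mappings must never cross
        cols = [mapping[d][p] for p in sorted(mapping[d])]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise AssertionError(f"{d}: non-monotonic consensus mapping")
    return ConsensusMap(
        n_columns=col0,
        mapping=mapping,
        residues=dict(residues),
        cys_columns=cys_columns,
    )


def project_variants(
    census: list[VariantRecord],
    cmap: ConsensusMap,
    domain_of=None,
) -> tuple[pd.DataFrame, list[VariantRecord]]:
    """Project Apple-domain missense variants (and polymorphisms) onto
    consensus columns.

    Each distinct protein change increments its column's tally; the
    dominant phenotype of a column is the modal phenotype of its
    variants (ties -> unknown). Variants whose residue is not covered by
    any domain mapping are returned in the excluded list.

    Returns ``(per_column, excluded)``; ``per_column`` has one row per
    consensus column with ``tally``, ``dominant_phenotype`` and
    ``cys_index``.
    """
    tallies: dict[int, list[Phenotype]] = defaultdict(list)
    excluded: list[VariantRecord] = []
    seen: set[tuple] = set()
    for rec in census:
        if rec.aggregate or rec.residue_hgvs is None:
            continue
        if rec.effect != Effect.MISSENSE:
            continue
        key = (rec.ref_aa, rec.residue_hgvs, rec.alt_aa)
        if key in seen:
            continue
        seen.add(key)
        col = None
        for d in cmap.mapping:
            col = cmap.column_of(d, rec.residue_hgvs)
            if col is not None:
                break
        if col is None:
            excluded.append(rec)
            continue
        tallies[col].append(rec.phenotype)

    rows = []
    for col in range(cmap.n_columns):
        phens = tallies.get(col, [])
        if phens:
            counts = pd.Series([p.value for p in phens]).value_counts()
            top = counts[counts == counts.max()]
            dominant = top.index[0] if len(top) == 1 else Phenotype.UNKNOWN.value
        else:
            dominant = ""
        rows.append(
            {
                "column": col,
                "cys_index": cmap.cys_columns.get(col, ""),
                "tally": len(phens),
                "dominant_phenotype": dominant,
            }
        )
    return pd.DataFrame(rows), excluded
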