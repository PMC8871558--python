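"""Signature-figure rendering in dash notation.

The classic CSI figure shows a reference sequence on the top line and, below
it, one row per taxon where a dash marks identity with the top line, a letter
marks a difference, and a blank cell marks a gap.  Taxa are grouped: the
CSI's carriers first, then the remaining in-group clades, then outgroups.
Rendering is lossless: :func:`reconstruct_slice` rebuilds the alignment slice
byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from html import escape

from csiscan.alignment_io import CladePartition, ProteinAlignment, UNPLACED
from csiscan.detection import CSICall

GAP_GLYPH = " "


class ConsistencyError(ValueError):
    """The CSI call does not match the alignment it claims to come from."""


@dataclass
class SignatureFigure:
    """A rendered signature excerpt.

    ``blocks`` maps a group label to ``(taxon, accession, rendered)`` rows in
    display order; the first row of the first block is the reference,
    rendered verbatim (no identity glyphs).  ``highlight`` is the indel span
    as column offsets within ``[display_start, display_end)``.
    """

    title: str
    display_start: int
    display_end: int
    reference_taxon: str
    blocks: list[tuple[str, list[tuple[str, str, str]]]] = field(default_factory=list)
    highlight: tuple[int, int] = (0, 0)
    identity_glyph: str = "-"

    @property
    def width(self) -> int:
        return self.display_end - self.display_start

    def to_text(self) -> str:
        """Plain-text figure with a caret line marking the indel span."""
        name_w = max((len(t) for _, rows in self.blocks for t, _, _ in rows),
                     default=10)
        acc_w = max((len(a) for _, rows in self.blocks for _, a, _ in rows),
                    default=0)
        lines = [self.title]
        pad = " " * (name_w + acc_w + 4)
        h0, h1 = self.highlight
        lines.append(pad + " " * h0 + "^" * (h1 - h0))
        for label, rows in self.blocks:
            lines.append(f"[{label}]")
            for taxon, acc, rendered in rows:
                lines.append(f"{taxon:<{name_w}}  {acc:<{acc_w}}  {rendered}")
            lines.append("")
        return "\n".join(lines).rstrip() + "\n"

    def to_html(self) -> str:
        """Minimal HTML emitter (monospace table, indel span emphasised)."""
        h0, h1 = self.highlight
        out = [f"<h3>{escape(self.title)}</h3>",
               "<table style='font-family:monospace'>"]
        for label, rows in self.blocks:
            out.append(f"<tr><th colspan=3>{escape(label)}</th></tr>")
            for taxon, acc, rendered in rows:
                pre, mid, post = rendered[:h0], rendered[h0:h1], rendered[h1:]
                cell = (escape(pre) + "<b>" + escape(mid) + "</b>" + escape(post))
                cell = cell.replace(" ", "&nbsp;")
                out.append(f"<tr><td>{escape(taxon)}</td><td>{escape(acc)}</td>"
                           f"<td>{cell}</td></tr>")
        out.append("</table>")
        return "\n".join(out)


def _render_row(row: str, reference: str, identity_glyph: str) -> str:
    out = []
    for ch, ref in zip(row, reference):
        if ch == "-":
            out.append(GAP_GLYPH)
        elif ch == ref:
            out.append(identity_glyph)
        else:
            out.append(ch)
    return "".join(out)


def render_signature(csi: CSICall, aln: ProteinAlignment,
                     partition: CladePartition, display_flank: int = 20,
                     strict_ascii: bool = False) -> SignatureFigure:
    """Render a CSI as a grouped dash-notation figure.

    ``display_flank`` columns are shown on each side of the indel (clipped at
    the alignment edges); changing it never alters glyphs inside the shared
    interval.  ``strict_ascii`` switches the identity glyph from ``-`` to
    ``.`` so plain-text output cannot be misread as gaps.
    """
    if csi.protein_id != aln.id:
        raise ConsistencyError(
            f"call is for protein {csi.protein_id!r}, alignment is {aln.id!r}")
    cand = csi.candidate
    if cand.end > aln.length or not (cand.gap_taxa | cand.residue_taxa) <= set(aln.taxa):
        raise ConsistencyError("call does not match alignment dimensions/taxa")
    lo = max(0, cand.start - display_flank)
    hi = min(aln.length, cand.end + display_flank)

    ref = csi.reference_taxon or next(iter(
        t for t in aln.taxa if t in cand.residue_taxa), aln.taxa[0])
    ref_slice = aln.rows[ref][lo:hi]
    identity = "." if strict_ascii else "-"

    def rendered(taxon: str) -> str:
        if taxon == ref:
            return ref_slice.replace("-", GAP_GLYPH)
        return _render_row(aln.rows[taxon][lo:hi], ref_slice, identity)

    def acc(taxon: str) -> str:
        return str(aln.metadata.get(taxon, {}).get("accession", ""))

    carriers = [t for t in aln.taxa if t in csi.carriers]
    outgroups = [t for t in aln.taxa
                 if t in partition.outgroups and t not in csi.carriers]
    rest = [t for t in aln.taxa if t not in csi.carriers and t not in outgroups]

    blocks: list[tuple[str, list[tuple[str, str, str]]]] = []
    if ref in carriers:
        # reference is always the first displayed row
        carriers.remove(ref)
        carriers.insert(0, ref)
    else:
        blocks.append(("reference", [(ref, acc(ref), rendered(ref))]))
        rest = [t for t in rest if t != ref]
        outgroups = [t for t in outgroups if t != ref]
    if carriers:
        blocks.append((csi.clade_label, [(t, acc(t), rendered(t)) for t in carriers]))
    grouping_level = csi.clade_level if csi.clade_level in partition.levels else None
    if rest:
        if grouping_level:
            by_label: dict[str, list[str]] = {}
            for t in rest:
                by_label.setdefault(
                    partition.levels[grouping_level].get(t, UNPLACED), []).append(t)
            for label in sorted(by_label):
                blocks.append((label, [(t, acc(t), rendered(t))
                                       for t in by_label[label]]))
        else:
            blocks.append(("other", [(t, acc(t), rendered(t)) for t in rest]))
    if outgroups:
        blocks.append(("outgroup", [(t, acc(t), rendered(t)) for t in outgroups]))

    kind = csi.polarity if csi.polarity in ("insertion", "deletion") else "indel"
    return SignatureFigure(
        title=f"{aln.id}: {cand.length} aa {kind} specific for {csi.clade_label}",
        display_start=lo,
        display_end=hi,
        reference_taxon=ref,
        blocks=blocks,
        highlight=(cand.start - lo, cand.end - lo),
        identity_glyph=identity,
    )


def reconstruct_slice(fig: SignatureFigure) -> dict[str, str]:
    """Invert a rendered figure back to the raw alignment slice.

    Returns taxon -> alignment characters over the display interval.  The
    inverse is exact: blanks become gaps, identity glyphs become the
    reference residue, letters stand for themselves.
    """
    rows: dict[str, str] = {}
    ref_rendered = None
    for _, block_rows in fig.blocks:
        for taxon, _, rendered in block_rows:
            if taxon == fig.reference_taxon:
                ref_rendered = rendered
                break
        if ref_rendered:
            break
    if ref_rendered is None:
        raise ConsistencyError("figure lacks its reference row")
    reference = ref_rendered.replace(GAP_GLYPH, "-")
    for _, block_rows in fig.blocks:
        for taxon, _, rendered in block_rows:
            if taxon == fig.reference_taxon:
                rows[taxon] = reference
                continue
            out = []
            for ch, ref in zip(rendered, reference):
                if ch == GAP_GLYPH:
                    out.append("-")
                elif ch == fig.identity_glyph:
                    out.append(ref)
                else:
                    out.append(ch)
            rows[taxon] = "".join(out)
    return rows
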