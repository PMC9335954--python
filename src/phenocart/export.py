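"""Render saved phenotype records for clinical notes and pipelines.

Three renderings of the same record: a minimal Rich Text Format table for
pasting into clinical notes, a TSV for bioinformatics pipelines, and a
Phenopacket-style JSON subset for interchange.  A token expander emulates
note-template links: every occurrence of a configured token (default
``.chophpo``) in note text is replaced by the rendered table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .store import PatientPhenotypeRecord

DEFAULT_TOKEN = ".chophpo"

_RTF_COLUMNS = ("HPO ID", "Term Name", "Negated", "Comment", "Date Added")
_TSV_COLUMNS = ("term_id", "term_name", "negated", "comment", "added_at")


@dataclass(frozen=True)
class RenderedTable:
    format: str  # rtf | tsv | markdown
    content: str
    row_count: int  # data rows, header excluded


def _rtf_escape(text: str) -> str:
    """Escape RTF control characters so arbitrary comments stay safe."""
    out = []
    for ch in text:
        if ch in "\\{}":
            out.append("\\" + ch)
        elif ord(ch) > 127:
            out.append(f"\\u{ord(ch)}?")
        elif ch == "\n":
            out.append(" ")
        else:
            out.append(ch)
    return "".join(out)


def _rtf_row(cells: tuple[str, ...]) -> str:
    borders = "".join(f"\\cellx{2000 * (i + 1)}" for i in range(len(cells)))
    body = "".join(_rtf_escape(c) + "\\cell " for c in cells)
    return "\\trowd" + borders + " " + body + "\\row\n"


def to_rtf_table(record: PatientPhenotypeRecord) -> RenderedTable:
    """Minimal valid RTF table: header row plus one row per annotation.

    The content begins ``{\\rtf1\\ansi`` and ends ``}``; each table row is
    terminated by ``\\row``, so the ``\\row`` count is annotation count + 1.
    """
    parts = ["{\\rtf1\\ansi\n", _rtf_row(_RTF_COLUMNS)]
    for a in record.annotations:
        parts.append(_rtf_row((
            a.term_id,
            a.term_name,
            "Yes" if a.negated else "",
            a.comment or "",
            a.added_at,
        )))
    parts.append("}")
    return RenderedTable(format="rtf", content="".join(parts),
                         row_count=len(record.annotations))


def _flatten(text: str | None) -> str:
    if not text:
        return ""
    return text.replace("\t", " ").replace("\r", " ").replace("\n", " ")


def to_tsv(record: PatientPhenotypeRecord) -> RenderedTable:
    """Tab-separated rendering; tabs/newlines inside comments become spaces."""
    lines = ["\t".join(_TSV_COLUMNS)]
    for a in record.annotations:
        lines.append("\t".join((
            a.term_id,
            _flatten(a.term_name),
            "true" if a.negated else "false",
            _flatten(a.comment),
            a.added_at,
        )))
    return RenderedTable(format="tsv", content="\n".join(lines) + "\n",
                         row_count=len(record.annotations))


def to_markdown(record: PatientPhenotypeRecord) -> RenderedTable:
    """GitHub-style table, handy for review outside the chart."""
    header = "| " + " | ".join(_RTF_COLUMNS) + " |"
    rule = "|" + "|".join(" --- " for _ in _RTF_COLUMNS) + "|"
    lines = [header, rule]
    for a in record.annotations:
        lines.append("| " + " | ".join((
            a.term_id, _flatten(a.term_name), "Yes" if a.negated else "",
            _flatten(a.comment), a.added_at)) + " |")
    return RenderedTable(format="markdown", content="\n".join(lines) + "\n",
                         row_count=len(record.annotations))


def to_phenopacket(record: PatientPhenotypeRecord) -> str:
    """Phenopacket-style JSON subset.

    One phenotypic feature per annotation, with ``excluded`` mirroring the
    negation flag and the ontology version carried in the metadata resource
    block.  This targets structural validity of these fields, not full
    schema conformance.
    """
    packet = {
        "id": record.patient_id,
        "phenotypicFeatures": [
            {
                "type": {"id": a.term_id, "label": a.term_name},
                "excluded": a.negated,
            }
            for a in record.annotations
        ],
        "metaData": {
            "created": record.saved_at,
            "resources": [{"id": "hp", "version": record.ontology_version}],
        },
    }
    return json.dumps(packet, indent=2, ensure_ascii=False)


def expand_token(note_text: str, record: PatientPhenotypeRecord,
                 token: str = DEFAULT_TOKEN, format: str = "rtf") -> str:
    """Replace every occurrence of *token* in note text with the record table.

    Rendered content is never rescanned, so expansion cannot recurse even if
    a comment happens to contain the token.  Text without the token is
    returned unchanged.
    """
    if not token:
        raise ValueError("token must be non-empty")
    renderers = {"rtf": to_rtf_table, "tsv": to_tsv, "markdown": to_markdown}
    try:
        table = renderers[format](record)
    except KeyError:
        raise ValueError(f"unknown format {format!r}") from None
    return note_text.replace(token, table.content)
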