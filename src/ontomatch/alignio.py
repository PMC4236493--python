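"""Reading and writing alignments in the Alignment RDF format used by the
OAEI evaluation campaigns, plus a flat TSV export.

Each correspondence is a Cell with entity1, entity2, a relation (always
equivalence here) and a confidence measure.  Files are written with cells
in sorted order so a run is byte-reproducible.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from xml.sax.saxutils import quoteattr

from .candidates import MappingTriple

__all__ = ["write_alignment", "read_alignment", "write_tsv"]

ALIGN_NS = "http://knowledgeweb.semanticweb.org/heterogeneity/alignment"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"


def write_alignment(mappings, path: str) -> None:
    """Serialize mappings (MappingTriples or (e1, e2[, score]) tuples) as
    Alignment RDF with deterministic cell order."""
    rows = []
    for m in mappings:
        if isinstance(m, MappingTriple):
            rows.append((m.e1, m.e2, m.score))
        else:
            e1, e2 = m[0], m[1]
            score = m[2] if len(m) > 2 else 1.0
            rows.append((e1, e2, float(score)))
    rows.sort()
    lines = [
        "<?xml version='1.0' encoding='utf-8' standalone='no'?>",
        f"<rdf:RDF xmlns='{ALIGN_NS}#'",
        f"         xmlns:rdf='{RDF_NS}'",
        "         xmlns:xsd='http://www.w3.org/2001/XMLSchema#'>",
        "<Alignment>",
        "  <xml>yes</xml>",
        "  <level>0</level>",
        "  <type>11</type>",
    ]
    for e1, e2, score in rows:
        lines.extend(
            [
                "  <map>",
                "    <Cell>",
                f"      <entity1 rdf:resource={quoteattr(e1)}/>",
                f"      <entity2 rdf:resource={quoteattr(e2)}/>",
                "      <relation>=</relation>",
                "      <measure rdf:datatype='http://www.w3.org/2001/XMLSchema#float'>"
                f"{score:.6f}</measure>",
                "    </Cell>",
                "  </map>",
            ]
        )
    lines.extend(["</Alignment>", "</rdf:RDF>", ""])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


def read_alignment(path: str) -> set[tuple[str, str, float]]:
    """Parse an Alignment RDF file into {(entity1, entity2, measure)}."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"malformed alignment file {path}: {exc}") from exc
    out: set[tuple[str, str, float]] = set()
    resource = f"{{{RDF_NS}}}resource"
    for cell in tree.iter(f"{{{ALIGN_NS}#}}Cell"):
        e1 = e2 = None
        measure = 1.0
        for child in cell:
            tag = child.tag.rsplit("}", 1)[-1]
            if tag == "entity1":
                e1 = child.get(resource)
            elif tag == "entity2":
                e2 = child.get(resource)
            elif tag == "measure" and child.text:
                measure = float(child.text)
        if e1 and e2:
            out.add((e1, e2, measure))
    if not out and tree.getroot().tag.rsplit("}", 1)[-1] != "RDF":
        raise ValueError(f"{path} is not an Alignment RDF document")
    return out


def write_tsv(mappings, path: str) -> None:
    """Flat export: entity1 <TAB> entity2 <TAB> score <TAB> provenance."""
    rows = []
    for m in mappings:
        if isinstance(m, MappingTriple):
            rows.append((m.e1, m.e2, m.score, m.provenance))
        else:
            rows.append((m[0], m[1], float(m[2]) if len(m) > 2 else 1.0, ""))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity1\tentity2\tscore\tprovenance\n")
        for e1, e2, score, prov in rows:
            fh.write(f"{e1}\t{e2}\t{score:.6f}\t{prov}\n")
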