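"""Reading and writing interaction files, identifier maps and networks.

Three line-oriented dialects are supported:

``simple_tsv``
    Tab-separated columns ``partner_a  partner_b  [source]``; an optional
    header line; ``#`` comment lines.

``biogrid_tab``
    A subset of the BioGRID tab formats: a header line names the columns;
    the official gene symbol columns give the partners and the
    experimental-system-type column distinguishes ``physical`` from
    ``genetic`` rows.  Genetic rows are dropped — including them would
    unbalance the network toward the screens' gene coverage.

``psimitab``
    A subset of PSI-MI TAB 2.5: columns 1–2 are ``db:accession``
    interactor identifiers; column 7 (detection method) is logged only.
    Unknown extra columns are ignored in both database dialects because
    snapshot formats drift across releases.
"""

from __future__ import annotations

import io as _io
import logging
from typing import Iterable, Optional, TextIO

from .graph import (
    IDMap,
    InteractionRecord,
    PPINetwork,
    ValidationError,
    canonicalize_pair,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "DIALECTS",
    "parse_interactions",
    "serialize_simple_tsv",
    "apply_idmap",
    "load_idmap",
    "to_sif",
    "to_graphml",
    "write_network",
]

DIALECTS = ("simple_tsv", "biogrid_tab", "psimitab")

_DEFAULT_SOURCE = {
    "simple_tsv": "simple_tsv",
    "biogrid_tab": "BioGRID",
    "psimitab": "psimitab",
}


class ParseError(ValueError):
    """A malformed line; carries the line number and dialect."""

    def __init__(self, message: str, line_number: int, dialect: str):
        super().__init__(f"{dialect} line {line_number}: {message}")
        self.line_number = line_number
        self.dialect = dialect


def _as_stream(stream: TextIO | str) -> TextIO:
    return _io.StringIO(stream) if isinstance(stream, str) else stream


def parse_interactions(
    stream: TextIO | str,
    dialect: str,
    source: Optional[str] = None,
) -> list[InteractionRecord]:
    """Parse one interaction file into records tagged with its source.

    Genetic-interaction rows (biogrid_tab) are dropped; every retained
    record has ``is_physical=True``.  ``source`` overrides the dialect's
    default source tag.
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    tag = source if source is not None else _DEFAULT_SOURCE[dialect]
    parser = {
        "simple_tsv": _parse_simple_tsv,
        "biogrid_tab": _parse_biogrid_tab,
        "psimitab": _parse_psimitab,
    }[dialect]
    return parser(_as_stream(stream), tag)


def _parse_simple_tsv(stream: TextIO, tag: str) -> list[InteractionRecord]:
    records = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "partner_a":  # optional header
            continue
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError("expected at least two tab-separated identifiers",
                             lineno, "simple_tsv")
        src = fields[2] if len(fields) >= 3 and fields[2] else tag
        records.append(
            InteractionRecord(fields[0], fields[1], frozenset({src}))
        )
    return records


def _find_column(header: list[str], *needles: str) -> Optional[int]:
    lowered = [h.strip().lstrip("#").strip().lower() for h in header]
    for needle in needles:
        for i, name in enumerate(lowered):
            if name == needle:
                return i
    return None


def _parse_biogrid_tab(stream: TextIO, tag: str) -> list[InteractionRecord]:
    records = []
    cols: Optional[tuple[int, int, int]] = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if cols is None:
            ia = _find_column(fields, "official symbol interactor a", "official_symbol_a")
            ib = _find_column(fields, "official symbol interactor b", "official_symbol_b")
            it = _find_column(
                fields, "experimental system type", "experimental_system_type"
            )
            if ia is None or ib is None or it is None:
                raise ParseError(
                    "header must name the official-symbol and "
                    "experimental-system-type columns",
                    lineno, "biogrid_tab",
                )
            cols = (ia, ib, it)
            continue
        if line.lstrip().startswith("#"):
            continue
        ia, ib, it = cols
        if len(fields) <= max(cols):
            raise ParseError("row has fewer columns than the header", lineno, "biogrid_tab")
        system_type = fields[it].strip().lower()
        if system_type == "genetic":
            continue
        if system_type != "physical":
            raise ParseError(
                f"unknown experimental system type {fields[it]!r}", lineno, "biogrid_tab"
            )
        a, b = fields[ia].strip(), fields[ib].strip()
        if not a or not b:
            raise ParseError("empty interactor symbol", lineno, "biogrid_tab")
        records.append(InteractionRecord(a, b, frozenset({tag})))
    return records


def _bare_accession(field: str, lineno: int) -> str:
    ident = field.strip()
    if not ident:
        raise ParseError("empty interactor identifier", lineno, "psimitab")
    # "uniprotkb:P07256" -> "P07256"; a bare accession passes through
    if ":" in ident:
        ident = ident.split(":", 1)[1]
    if not ident:
        raise ParseError(f"no accession in {field!r}", lineno, "psimitab")
    return ident


def _parse_psimitab(stream: TextIO, tag: str) -> list[InteractionRecord]:
    records = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError("expected tab-separated PSI-MI TAB columns", lineno, "psimitab")
        a = _bare_accession(fields[0], lineno)
        b = _bare_accession(fields[1], lineno)
        if len(fields) >= 7 and fields[6].strip():
            logger.debug("psimitab line %d detection method: %s", lineno, fields[6])
        records.append(InteractionRecord(a, b, frozenset({tag})))
    return records


def serialize_simple_tsv(records: Iterable[InteractionRecord]) -> str:
    """Write records as simple_tsv, one ordered pair per line."""
    lines = ["partner_a\tpartner_b\tsource"]
    for rec in records:
        a, b = rec.pair()
        src = ";".join(sorted(rec.sources))
        lines.append(f"{a}\t{b}\t{src}")
    return "\n".join(lines) + "\n"


def apply_idmap(
    records: Iterable[InteractionRecord],
    idmap: IDMap,
    on_unmapped: str = "drop",
) -> list[InteractionRecord]:
    """Replace every partner by its canonical name.

    ``on_unmapped='drop'`` excludes records with an unknown alias and
    logs a warning; ``'fail'`` raises listing every missing alias.
    """
    if on_unmapped not in ("drop", "fail"):
        raise ValidationError("on_unmapped must be 'drop' or 'fail'")
    out: list[InteractionRecord] = []
    missing: set[str] = set()
    dropped = 0
    for rec in records:
        ca = idmap.get(rec.partner_a)
        cb = idmap.get(rec.partner_b)
        if ca is None or cb is None:
            for ident, mapped in ((rec.partner_a, ca), (rec.partner_b, cb)):
                if mapped is None:
                    missing.add(ident)
            dropped += 1
            continue
        a, b = canonicalize_pair(ca, cb)
        out.append(
            InteractionRecord(a, b, rec.sources, rec.evidence_count, rec.is_physical)
        )
    if missing:
        if on_unmapped == "fail":
            raise ValidationError(
                f"unmapped aliases: {', '.join(sorted(missing))}"
            )
        logger.warning(
            "dropped %d record(s) with %d unmapped alias(es): %s",
            dropped, len(missing), ", ".join(sorted(missing)),
        )
    return out


def load_idmap(stream: TextIO | str) -> IDMap:
    """Load an alias -> canonical TSV (``alias\\tcanonical``, # comments)."""
    idmap = IDMap()
    for lineno, raw in enumerate(_as_stream(stream), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "alias":
            continue
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ParseError("expected alias<TAB>canonical", lineno, "idmap")
        idmap.add(fields[0].strip(), fields[1].strip())
    return idmap


def to_sif(network: PPINetwork, interaction_type: str = "pp") -> str:
    """SIF export with stable lexicographic ordering."""
    lines = [f"{a}\t{interaction_type}\t{b}" for a, b in network.edges]
    connected = {n for e in network.edges for n in e}
    lines.extend(n for n in network.nodes if n not in connected)
    return "\n".join(lines) + ("\n" if lines else "")


def to_graphml(network: PPINetwork) -> str:
    """GraphML export with stable node and edge ordering."""
    import networkx as nx

    g = nx.Graph()
    for n in network.nodes:
        attrs = {
            k: v for k, v in network.g.nodes[n].items()
            if isinstance(v, (bool, int, float, str))
        }
        g.add_node(n, **attrs)
    for a, b in network.edges:
        data = network.g.edges[a, b]
        g.add_edge(a, b, sources=";".join(sorted(data["sources"])),
                   evidence=int(data["evidence"]))
    return "\n".join(nx.generate_graphml(g)) + "\n"


def write_network(network: PPINetwork, path: str, fmt: str = "sif") -> None:
    if fmt == "sif":
        text = to_sif(network)
    elif fmt == "graphml":
        text = to_graphml(network)
    elif fmt == "simple_tsv":
        text = serialize_simple_tsv(network.to_records())
    else:
        raise ValidationError(f"unknown network format {fmt!r}")
    with open(path, "w") as fh:
        fh.write(text)
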