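"""Minimal dialect of the Standard DNA Damage (SDD) text format.

The SDD format is the community convention for reporting DNA damage from
track-structure simulations: a key/value header block terminated by a sentinel
line, followed by one semicolon-separated data line per damage site.  Damage
is grouped into 10-bp "damage sites"; each line carries the lesion counts
(strand breaks per strand, base damages), the double-strand-break flag and the
direct/indirect cause split that downstream complexity scoring consumes.

This module implements the minimal field set needed by the rest of the
package.  The dialect written here is canonical: reading a canonical file and
writing it back reproduces the data section byte-for-byte.  Unknown header
keys are preserved verbatim in :attr:`SDDHeader.free_fields` (a warning is
logged), so foreign metadata survives a round trip.

Data line layout (7 fields, ``;``-separated, comma-separated sub-fields)::

    track_id; chromosome_id; genomic_position_bp; x,y,z; sb1,sb2,bd; dsb; dir,ind

Coordinate conventions: genomic positions are 0-based site-start indices;
spatial positions are um in a nucleus-centered frame.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

logger = logging.getLogger(__name__)

HEADER_SENTINEL = "***EndOfHeader***;"

# header keys the package interprets; everything else goes to free_fields
_KNOWN_KEYS = {
    "Simulator": "simulator_name",
    "Dose or fluence": "dose_or_fluence",
    "Particle": "particle",
    "Energy": "energy_MeV",
    "Damage definition": "site_definition_bp",
}


class SDDFormatError(ValueError):
    """Malformed header or file structure; the message names the line."""


class SDDRecordError(ValueError):
    """Malformed data record; the message carries the line number."""


@dataclass
class SDDHeader:
    simulator_name: str = ""
    dose_or_fluence: float = 0.0
    particle: str = ""
    energy_MeV: float = 0.0
    site_definition_bp: int = 10
    free_fields: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.site_definition_bp < 1:
            raise ValueError(
                f"site_definition_bp must be >= 1, got {self.site_definition_bp}"
            )


@dataclass
class DamageSiteRecord:
    """One 10-bp damage site.

    ``has_dsb`` may be supplied explicitly (trusted when present in a file) or
    derived: a double-strand break requires at least one strand break on each
    strand within the site.  ``cause_direct``/``cause_indirect`` partition the
    total lesion count by physical origin; both zero means the cause split is
    unavailable.
    """

    track_id: int
    chromosome_id: int
    genomic_position_bp: int
    spatial_position_um: tuple[float, float, float]
    n_sb_strand1: int
    n_sb_strand2: int
    n_bd: int
    has_dsb: bool
    cause_direct: int = 0
    cause_indirect: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sb_strand1", "n_sb_strand2", "n_bd",
                     "cause_direct", "cause_indirect"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.genomic_position_bp < 0:
            raise ValueError(
                f"genomic_position_bp must be >= 0, got {self.genomic_position_bp}"
            )
        if self.total_lesions < 1:
            raise ValueError("a damage site must contain at least one lesion")
        if self.has_dsb and not (self.n_sb_strand1 >= 1 and self.n_sb_strand2 >= 1):
            raise ValueError("has_dsb requires >= 1 strand break on each strand")
        if self.cause_direct + self.cause_indirect not in (0, self.total_lesions):
            raise ValueError(
                "cause_direct + cause_indirect must equal the total lesion count "
                "when cause information is present"
            )

    @property
    def total_lesions(self) -> int:
        return self.n_sb_strand1 + self.n_sb_strand2 + self.n_bd

    @property
    def has_cause_info(self) -> bool:
        return self.cause_direct + self.cause_indirect > 0


def derive_has_dsb(n_sb_strand1: int, n_sb_strand2: int) -> bool:
    """SDD site convention: a DSB needs a break on each strand in the site."""
    return n_sb_strand1 >= 1 and n_sb_strand2 >= 1


def _fmt_float(x: float) -> str:
    # shortest repr: exact value round trip AND byte-stable re-serialization
    return repr(float(x))


def _parse_header(lines: list[str]) -> tuple[SDDHeader, int]:
    kwargs: dict = {}
    free: dict[str, str] = {}
    for i, raw in enumerate(lines):
        line = raw.rstrip("\n")
        if line.strip() == HEADER_SENTINEL:
            try:
                return SDDHeader(**kwargs, free_fields=free), i + 1
            except (TypeError, ValueError) as exc:
                raise SDDFormatError(f"invalid header values: {exc}") from exc
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if "," not in line:
            raise SDDFormatError(
                f"header line {i + 1} is not 'Key, value;': {line!r}"
            )
        key, _, value = line.partition(",")
        key = key.strip()
        value = value.strip().rstrip(";").strip()
        if key in _KNOWN_KEYS:
            attr = _KNOWN_KEYS[key]
            try:
                if attr == "site_definition_bp":
                    kwargs[attr] = int(value)
                elif attr in ("dose_or_fluence", "energy_MeV"):
                    kwargs[attr] = float(value)
                else:
                    kwargs[attr] = value
            except ValueError as exc:
                raise SDDFormatError(
                    f"header line {i + 1}: cannot parse value for {key!r}: {value!r}"
                ) from exc
        else:
            logger.warning("unrecognized SDD header key %r preserved as free text", key)
            free[key] = value
    raise SDDFormatError(
        f"header not terminated by {HEADER_SENTINEL!r} before end of input"
    )


def _parse_int(token: str, what: str, lineno: int) -> int:
    token = token.strip()
    try:
        value = int(token)
    except ValueError as exc:
        raise SDDRecordError(
            f"line {lineno}: {what} is not an integer: {token!r}"
        ) from exc
    return value


def _parse_record(line: str, lineno: int) -> DamageSiteRecord:
    fields = [f.strip() for f in line.rstrip(";").split(";")]
    if len(fields) != 7:
        raise SDDRecordError(
            f"line {lineno}: expected 7 ';'-separated fields, got {len(fields)}"
        )
    track_id = _parse_int(fields[0], "track_id", lineno)
    chromosome_id = _parse_int(fields[1], "chromosome_id", lineno)
    position = _parse_int(fields[2], "genomic_position_bp", lineno)
    try:
        x, y, z = (float(t) for t in fields[3].split(","))
    except ValueError as exc:
        raise SDDRecordError(
            f"line {lineno}: spatial position must be 'x,y,z': {fields[3]!r}"
        ) from exc
    counts = fields[4].split(",")
    if len(counts) != 3:
        raise SDDRecordError(
            f"line {lineno}: lesion counts must be 'sb1,sb2,bd': {fields[4]!r}"
        )
    sb1 = _parse_int(counts[0], "n_sb_strand1", lineno)
    sb2 = _parse_int(counts[1], "n_sb_strand2", lineno)
    bd = _parse_int(counts[2], "n_bd", lineno)
    dsb_token = fields[5]
    if dsb_token == "":
        has_dsb = derive_has_dsb(sb1, sb2)
    else:
        has_dsb = bool(_parse_int(dsb_token, "dsb flag", lineno))
    if fields[6] == "":
        direct, indirect = 0, 0
    else:
        cause = fields[6].split(",")
        if len(cause) != 2:
            raise SDDRecordError(
                f"line {lineno}: cause must be 'direct,indirect': {fields[6]!r}"
            )
        direct = _parse_int(cause[0], "cause_direct", lineno)
        indirect = _parse_int(cause[1], "cause_indirect", lineno)
    try:
        return DamageSiteRecord(
            track_id=track_id,
            chromosome_id=chromosome_id,
            genomic_position_bp=position,
            spatial_position_um=(x, y, z),
            n_sb_strand1=sb1,
            n_sb_strand2=sb2,
            n_bd=bd,
            has_dsb=has_dsb,
            cause_direct=direct,
            cause_indirect=indirect,
        )
    except ValueError as exc:
        raise SDDRecordError(f"line {lineno}: {exc}") from exc


def read_sdd(path_or_stream: str | Path | TextIO) -> tuple[SDDHeader, list[DamageSiteRecord]]:
    """Parse an SDD file (or open text stream) into a header and records.

    Records come back in file order; group by ``record.track_id`` to recover
    per-track structure.
    """
    if isinstance(path_or_stream, (str, Path)):
        with open(path_or_stream) as fh:
            lines = fh.readlines()
    else:
        lines = path_or_stream.readlines()
    header, data_start = _parse_header(lines)
    records = []
    for offset, raw in enumerate(lines[data_start:]):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        records.append(_parse_record(line, data_start + offset + 1))
    return header, records


def _record_line(r: DamageSiteRecord) -> str:
    x, y, z = r.spatial_position_um
    cause = f"{r.cause_direct},{r.cause_indirect}" if r.has_cause_info else "0,0"
    return (
        f"{r.track_id}; {r.chromosome_id}; {r.genomic_position_bp}; "
        f"{_fmt_float(x)},{_fmt_float(y)},{_fmt_float(z)}; "
        f"{r.n_sb_strand1},{r.n_sb_strand2},{r.n_bd}; "
        f"{int(r.has_dsb)}; {cause};"
    )


def write_sdd(
    header: SDDHeader,
    records: Iterable[DamageSiteRecord],
    path_or_stream: str | Path | TextIO,
) -> None:
    """Serialize header and records in the canonical dialect.

    Records are validated before any output is written, so a validation error
    never leaves a partial file behind.
    """
    records = list(records)  # dataclass __post_init__ has already validated
    buf = io.StringIO()
    buf.write(f"Simulator, {header.simulator_name};\n")
    buf.write(f"Dose or fluence, {_fmt_float(header.dose_or_fluence)};\n")
    buf.write(f"Particle, {header.particle};\n")
    buf.write(f"Energy, {_fmt_float(header.energy_MeV)};\n")
    buf.write(f"Damage definition, {header.site_definition_bp};\n")
    for key, value in header.free_fields.items():
        buf.write(f"{key}, {value};\n")
    buf.write(HEADER_SENTINEL + "\n")
    for r in records:
        buf.write(_record_line(r) + "\n")
    text = buf.getvalue()
    if isinstance(path_or_stream, (str, Path)):
        with open(path_or_stream, "w") as fh:
            fh.write(text)
    else:
        path_or_stream.write(text)


def group_by_track(records: Iterable[DamageSiteRecord]) -> dict[int, list[DamageSiteRecord]]:
    """Order-preserving grouping of records by track id."""
    groups: dict[int, list[DamageSiteRecord]] = {}
    for r in records:
        groups.setdefault(r.track_id, []).append(r)
    return groups
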