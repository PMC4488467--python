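"""Readers and writers: TPS landmark files, genotype CSV, result tables.

The TPS dialect handled here is the plain-text format produced by standard
landmark-digitizing software: repeated blocks of ``LM=<n>`` followed by
``n`` lines of two whitespace-separated coordinates, optionally followed by
``IMAGE=``, ``ID=`` and ``SCALE=`` lines (keys case-insensitive, blank lines
ignored). Coordinates are stored in file units, y axis up; no image-row
flipping is performed, since digitizers differ.

Genotype tables travel as CSV with header
``specimen_id,colony_id,role,<locus>_a,<locus>_b,...``; integer allele
codes, 0 = missing, allele pairs canonicalized (min, max) on read; the
``role`` column distinguishes ``queen`` and ``worker`` rows.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import MultilocusGenotype
from .superimpose import LandmarkConfiguration

__all__ = [
    "TpsRecord",
    "read_tps",
    "write_tps",
    "tps_to_configurations",
    "configurations_to_tps",
    "read_genotypes",
    "write_genotypes",
]


@dataclass
class TpsRecord:
    """One TPS block: landmark coordinates plus optional metadata."""

    coordinates: np.ndarray
    id: str = ""
    image: str | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValueError("TPS coordinates must be (n, 2)")
        if self.scale is not None and self.scale <= 0:
            raise ValueError("SCALE must be positive")

    @property
    def landmark_count(self) -> int:
        return self.coordinates.shape[0]


def _as_text_stream(stream):
    if isinstance(stream, str) and "\n" not in stream:
        return open(stream), True
    if isinstance(stream, str):
        return io.StringIO(stream), True
    return stream, False


def read_tps(stream) -> list[TpsRecord]:
    """Parse a TPS stream (file path, text, or file object) into records.

    Raises ``ValueError`` with the offending line number on malformed input
    (wrong coordinate-line count, non-numeric coordinates).
    """
    fh, close = _as_text_stream(stream)
    try:
        records: list[TpsRecord] = []
        coords: list[list[float]] = []
        expect = 0
        meta: dict = {}
        in_block = False

        def flush(lineno):
            nonlocal in_block
            if not in_block:
                return
            if len(coords) != expect:
                raise ValueError(
                    f"line {lineno}: expected {expect} coordinate lines, "
                    f"got {len(coords)}"
                )
            records.append(
                TpsRecord(
                    np.asarray(coords, dtype=float).reshape(expect, 2),
                    id=meta.get("id", ""),
                    image=meta.get("image"),
                    scale=meta.get("scale"),
                )
            )
            coords.clear()
            meta.clear()
            in_block = False

        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            key, sep, value = line.partition("=")
            key_upper = key.strip().upper()
            if sep and key_upper == "LM":
                flush(lineno)
                try:
                    expect = int(value.strip())
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: bad LM count {value!r}") from exc
                in_block = True
            elif sep and key_upper in ("ID", "IMAGE", "SCALE") and not _looks_numeric_pair(line):
                if not in_block:
                    raise ValueError(f"line {lineno}: {key_upper}= outside a block")
                if key_upper == "SCALE":
                    try:
                        meta["scale"] = float(value.strip())
                    except ValueError as exc:
                        raise ValueError(
                            f"line {lineno}: bad SCALE {value!r}"
                        ) from exc
                else:
                    meta[key_upper.lower()] = value.strip()
            else:
                if not in_block:
                    raise ValueError(f"line {lineno}: coordinates before LM=")
                parts = line.split()
                if len(parts) != 2:
                    raise ValueError(
                        f"line {lineno}: expected two coordinates, got {line!r}"
                    )
                try:
                    coords.append([float(parts[0]), float(parts[1])])
                except ValueError as exc:
                    raise ValueError(
                        f"line {lineno}: non-numeric coordinate in {line!r}"
                    ) from exc
                if len(coords) > expect:
                    raise ValueError(
                        f"line {lineno}: more than LM={expect} coordinate lines"
                    )
        flush("end of input")
        return records
    finally:
        if close:
            fh.close()


def _looks_numeric_pair(line: str) -> bool:
    parts = line.split()
    if len(parts) != 2:
        return False
    try:
        float(parts[0]), float(parts[1])
    except ValueError:
        return False
    return True


def write_tps(records: list[TpsRecord]) -> str:
    """Serialize records in a canonical dialect (6-decimal coordinates)."""
    out = []
    for rec in records:
        out.append(f"LM={rec.landmark_count}")
        for x, y in rec.coordinates:
            out.append(f"{x:.6f} {y:.6f}")
        if rec.image is not None:
            out.append(f"IMAGE={rec.image}")
        out.append(f"ID={rec.id}")
        if rec.scale is not None:
            out.append(f"SCALE={rec.scale:.6f}")
    return "\n".join(out) + ("\n" if out else "")


def tps_to_configurations(
    records: list[TpsRecord], scale_coordinates: bool = True
) -> list[LandmarkConfiguration]:
    """Convert TPS records to landmark configurations.

    The record ``ID`` is parsed as ``specimen[@colony][/m<mounting>.d<digit>]``
    if it carries pipeline provenance; otherwise it becomes the specimen id.
    ``SCALE`` multiplies the coordinates when ``scale_coordinates`` is set.
    """
    configs = []
    for rec in records:
        coords = rec.coordinates
        if scale_coordinates and rec.scale is not None:
            coords = coords * rec.scale
        specimen, colony, mounting, digit = rec.id, "", 0, 0
        if "/" in specimen:
            specimen, _, rep = specimen.partition("/")
            try:
                m_part, d_part = rep.split(".")
                mounting = int(m_part.lstrip("m"))
                digit = int(d_part.lstrip("d"))
            except ValueError as exc:
                raise ValueError(f"bad replicate suffix in ID {rec.id!r}") from exc
        if "@" in specimen:
            specimen, _, colony = specimen.partition("@")
        configs.append(
            LandmarkConfiguration(
                coords,
                specimen_id=specimen,
                colony_id=colony,
                mounting=mounting,
                digitization=digit,
                scale=rec.scale,
            )
        )
    return configs


def configurations_to_tps(configs: list[LandmarkConfiguration]) -> list[TpsRecord]:
    records = []
    for c in configs:
        ident = c.specimen_id
        if c.colony_id:
            ident += f"@{c.colony_id}"
        if c.mounting or c.digitization:
            ident += f"/m{c.mounting}.d{c.digitization}"
        records.append(TpsRecord(c.coords.copy(), id=ident, scale=c.scale))
    return records


def read_genotypes(
    source,
) -> tuple[list[MultilocusGenotype], dict[str, MultilocusGenotype]]:
    """Read a genotype CSV into (workers, queens-by-colony).

    Expects columns ``specimen_id, colony_id, role`` and paired
    ``<locus>_a/<locus>_b`` allele columns; unknown roles and odd allele
    columns raise.
    """
    df = pd.read_csv(source, dtype={"specimen_id": str, "colony_id": str})
    required = {"specimen_id", "colony_id", "role"}
    if not required <= set(df.columns):
        raise ValueError(f"genotype CSV must have columns {sorted(required)}")
    allele_cols = [c for c in df.columns if c.endswith(("_a", "_b"))]
    loci = []
    for col in allele_cols:
        if col.endswith("_a"):
            name = col[:-2]
            if f"{name}_b" not in df.columns:
                raise ValueError(f"locus {name}: missing {name}_b column")
            loci.append(name)
        elif f"{col[:-2]}_a" not in df.columns:
            raise ValueError(f"locus {col[:-2]}: missing {col[:-2]}_a column")
    if not loci:
        raise ValueError("no allele columns found")

    workers: list[MultilocusGenotype] = []
    queens: dict[str, MultilocusGenotype] = {}
    for _, row in df.iterrows():
        geno = MultilocusGenotype(
            str(row["specimen_id"]),
            str(row["colony_id"]),
            {
                name: (
                    int(0 if pd.isna(row[f"{name}_a"]) else row[f"{name}_a"]),
                    int(0 if pd.isna(row[f"{name}_b"]) else row[f"{name}_b"]),
                )
                for name in loci
            },
        )
        role = str(row["role"]).lower()
        if role == "queen":
            queens[geno.colony_id] = geno
        elif role == "worker":
            workers.append(geno)
        else:
            raise ValueError(f"unknown role {row['role']!r} for {geno.specimen_id}")
    return workers, queens


def write_genotypes(
    workers: list[MultilocusGenotype],
    queens: dict[str, MultilocusGenotype],
    path_or_buf=None,
):
    """Write workers and queens to the genotype CSV dialect."""
    everyone = [(q, "queen") for q in queens.values()] + [
        (w, "worker") for w in workers
    ]
    if not everyone:
        raise ValueError("nothing to write")
    loci = list(everyone[0][0].loci)
    rows = []
    for geno, role in everyone:
        row = {
            "specimen_id": geno.specimen_id,
            "colony_id": geno.colony_id,
            "role": role,
        }
        for name in loci:
            row[f"{name}_a"], row[f"{name}_b"] = geno.loci[name]
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.to_csv(path_or_buf, index=False)
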