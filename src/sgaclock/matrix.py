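"""Biopsy x character binary SGA matrices and per-biopsy metadata.

A *character* is a genomic interval with exact shared breakpoints across
all biopsies of one individual (0-based, half-open bp coordinates),
optionally tagged with a haplotype-resolved state form so that e.g. the
AA and BB copy-neutral-LOH forms of the same interval are distinct
characters.  Entries are 0 (normal AB state) / 1 (any SGA state).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class BiopsyMeta:
    """Sampling metadata for one biopsy (or blood control)."""

    individual_id: str
    biopsy_id: str
    sample_time: float  # years since baseline endoscopy
    level: float  # cm above the gastroesophageal junction
    nsaid_status: str  # "on" | "off" at sampling
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.nsaid_status not in ("on", "off"):
            raise ValueError("nsaid_status must be 'on' or 'off'")
        if self.sample_time < 0:
            raise ValueError("sample_time is measured in years since baseline (>= 0)")


@dataclass(frozen=True)
class Character:
    """One matrix column: an exact-breakpoint interval plus state form."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    form: str = ""  # haplotype/state form tag ("" when unresolved)

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    @property
    def label(self) -> str:
        base = f"{self.chrom}:{self.start}-{self.end}"
        return f"{base}|{self.form}" if self.form else base

    @classmethod
    def from_label(cls, label: str) -> "Character":
        form = ""
        if "|" in label:
            label, form = label.split("|", 1)
        chrom, span = label.rsplit(":", 1)
        start, end = span.split("-")
        return cls(chrom, int(start), int(end), form)


@dataclass
class SgaMatrix:
    """Binary biopsies x characters matrix with sizes and metadata links."""

    biopsy_ids: list[str]
    characters: list[Character]
    data: np.ndarray  # shape (n_biopsies, n_characters), uint8
    meta: dict[str, BiopsyMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.shape != (len(self.biopsy_ids), len(self.characters)):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.biopsy_ids)} biopsies x {len(self.characters)} characters"
            )
        if len(set(self.biopsy_ids)) != len(self.biopsy_ids):
            raise ValueError("duplicate biopsy ids")

    # ---------------------------------------------------------------- access
    @property
    def n_biopsies(self) -> int:
        return len(self.biopsy_ids)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def sizes_bp(self) -> np.ndarray:
        return np.array([c.size_bp for c in self.characters], dtype=np.int64)

    def row(self, biopsy_id: str) -> np.ndarray:
        return self.data[self.biopsy_ids.index(biopsy_id)]

    def select_characters(self, keep: np.ndarray) -> "SgaMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return SgaMatrix(
            biopsy_ids=list(self.biopsy_ids),
            characters=[self.characters[i] for i in idx],
            data=self.data[:, idx].copy(),
            meta=dict(self.meta),
        )

    def select_biopsies(self, ids: list[str]) -> "SgaMatrix":
        idx = [self.biopsy_ids.index(b) for b in ids]
        return SgaMatrix(
            biopsy_ids=list(ids),
            characters=list(self.characters),
            data=self.data[idx, :].copy(),
            meta={b: self.meta[b] for b in ids if b in self.meta},
        )

    def drop_empty_characters(self) -> "SgaMatrix":
        return self.select_characters(self.data.any(axis=0))

    # ------------------------------------------------------------------- I/O
    def to_tsv(self, path: str | Path) -> None:
        """Lossless tab-delimited dump (character table + matrix block).

        Lines starting ``#character`` carry the per-column interval, form
        and size; coordinates are 0-based half-open.
        """
        path = Path(path)
        with path.open("w") as fh:
            fh.write("#coords\t0-based half-open\n")
            for c in self.characters:
                fh.write(
                    f"#character\t{c.label}\t{c.chrom}\t{c.start}\t{c.end}\t"
                    f"{c.form}\t{c.size_bp}\n"
                )
            for m in self.meta.values():
                fh.write(
                    f"#biopsy\t{m.biopsy_id}\t{m.individual_id}\t{m.sample_time!r}\t"
                    f"{m.level!r}\t{m.nsaid_status}\t{int(m.is_control)}\n"
                )
            fh.write("\t".join(["biopsy_id"] + [c.label for c in self.characters]) + "\n")
            for bid, row in zip(self.biopsy_ids, self.data):
                fh.write("\t".join([bid] + [str(int(v)) for v in row]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SgaMatrix":
        characters: list[Character] = []
        meta: dict[str, BiopsyMeta] = {}
        biopsy_ids: list[str] = []
        rows: list[list[int]] = []
        header: list[str] | None = None
        with Path(path).open() as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#character\t"):
                    _, label, chrom, start, end, form, _size = line.split("\t")
                    characters.append(Character(chrom, int(start), int(end), form))
                elif line.startswith("#biopsy\t"):
                    _, bid, ind, t, lvl, status, ctrl = line.split("\t")
                    meta[bid] = BiopsyMeta(ind, bid, float(t), float(lvl), status, bool(int(ctrl)))
                elif line.startswith("#"):
                    continue
                elif header is None:
                    header = line.split("\t")[1:]
                else:
                    parts = line.split("\t")
                    biopsy_ids.append(parts[0])
                    rows.append([int(v) for v in parts[1:] if v != ""])
        if header is None:
            raise ValueError(f"no matrix block found in {path}")
        if not characters:
            characters = [Character.from_label(lbl) for lbl in header]
        if [c.label for c in characters] != header:
            raise ValueError("character table does not match matrix header")
        data = (
            np.array(rows, dtype=np.uint8)
            if rows
            else np.zeros((0, len(characters)), dtype=np.uint8)
        )
        if data.size and data.shape[1] != len(characters):
            raise ValueError("matrix row width does not match character count")
        return cls(biopsy_ids, characters, data, meta)

    def to_nexus(self, path: str | Path) -> None:
        """NEXUS DATA block with binary symbols (readable by dendropy)."""
        with Path(path).open("w") as fh:
            fh.write("#NEXUS\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={self.n_biopsies} NCHAR={max(self.n_characters, 1)};\n")
            fh.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;\n')
            fh.write("  MATRIX\n")
            for bid, row in zip(self.biopsy_ids, self.data):
                seq = "".join(str(int(v)) for v in row) or "0"
                fh.write(f"    {bid.replace(' ', '_')}  {seq}\n")
            fh.write("  ;\nEND;\n")

    def to_bed(self, path: str | Path) -> None:
        """BED (0-based half-open) of the per-character intervals."""
        with Path(path).open("w") as fh:
            fh.write('track name="sga_characters" description="0-based half-open"\n')
            for c in self.characters:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.label}\n")


def read_sample_sheet(path: str | Path) -> dict[str, BiopsyMeta]:
    """Tab-delimited sample sheet -> biopsy_id -> :class:`BiopsyMeta`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    out: dict[str, BiopsyMeta] = {}
    for rec in df.itertuples(index=False):
        out[str(rec.biopsy_id)] = BiopsyMeta(
            individual_id=str(rec.individual_id),
            biopsy_id=str(rec.biopsy_id),
            sample_time=float(rec.sample_time),
            level=float(rec.level),
            nsaid_status=str(rec.nsaid_status),
            is_control=bool(rec.is_control),
        )
    return out


def write_sample_sheet(meta: dict[str, BiopsyMeta], path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "biopsy_id": m.biopsy_id,
                "individual_id": m.individual_id,
                "sample_time": m.sample_time,
                "level": m.level,
                "nsaid_status": m.nsaid_status,
                "is_control": m.is_control,
            }
            for m in meta.values()
        ]
    )
    df.to_csv(path, sep="\t", index=False)
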