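"""Reading and writing PLINK 1 binary triplets (.bed/.bim/.fam).

The .bed file is variant-major: after a 3-byte header (magic ``6C 1B``,
mode ``01``) each variant occupies ``ceil(n_samples/4)`` bytes, four
samples packed per byte, lowest-order bit pair first.  The 2-bit codes
are interpreted with the usual PLINK convention where ``00`` means
homozygous for the A1 allele of the .bim row.  Dosage here counts copies
of A1, so ``00 -> 2``, ``10 -> 1``, ``11 -> 0`` and ``01`` is missing.

Missing genotypes are stored as :data:`MISSING` (-1) in the dosage
matrix, which is an int8 array of shape (n_samples, n_variants).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

_MAGIC = bytes([0x6C, 0x1B])
_MODE_VARIANT_MAJOR = 0x01

#: 2-bit PLINK code -> A1 dosage
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
#: A1 dosage (index 0,1,2; 3 used for missing) -> 2-bit PLINK code
_DOSAGE_TO_CODE = np.array([3, 2, 0, 1], dtype=np.uint8)

_CHROM_ALIASES = {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}

VARIANT_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]
SAMPLE_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]

CONTROL, CASE = 1, 2


class PlinkError(ValueError):
    """Raised for malformed or inconsistent PLINK triplets."""


@dataclasses.dataclass
class GenotypeMatrix:
    """A diploid biallelic cohort: dosages plus variant and sample tables.

    Attributes
    ----------
    dosages : int8 array, samples x variants
        Copies of the A1 allele (0/1/2), or :data:`MISSING`.
    variants : DataFrame with columns chrom, snp, cm, pos, a1, a2
        One row per .bim line, in map order (= dosage column order).
    samples : DataFrame with columns fid, iid, father, mother, sex, phenotype
        One row per .fam line.  Phenotype coding: 1 control, 2 case,
        0 or -9 missing.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise PlinkError("dosages must be 2-dimensional")
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise PlinkError(
                f"sample table has {len(self.samples)} rows for {n} dosage rows"
            )
        if len(self.variants) != m:
            raise PlinkError(
                f"variant table has {len(self.variants)} rows for {m} dosage columns"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise PlinkError("dosages must be 0, 1, 2 or MISSING")
        if self.variants["snp"].duplicated().any():
            raise PlinkError("duplicate snp ids in variant table")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def phenotype(self) -> np.ndarray:
        """Phenotype codes (1 control / 2 case / 0,-9 missing) as int array."""
        return self.samples["phenotype"].to_numpy(dtype=int)

    def case_mask(self) -> np.ndarray:
        return self.phenotype == CASE

    def control_mask(self) -> np.ndarray:
        return self.phenotype == CONTROL

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset samples by positional index (order preserved)."""
        return GenotypeMatrix(
            self.dosages[np.asarray(index)],
            self.variants.copy(),
            self.samples.iloc[np.asarray(index)].reset_index(drop=True),
        )

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset variants by positional index (order preserved)."""
        return GenotypeMatrix(
            self.dosages[:, np.asarray(index)],
            self.variants.iloc[np.asarray(index)].reset_index(drop=True),
            self.samples.copy(),
        )

    def variant_index(self, snp_ids) -> np.ndarray:
        """Positional indices of the given snp ids (raises on unknown ids)."""
        lookup = pd.Index(self.variants["snp"])
        idx = lookup.get_indexer(list(snp_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"unknown snp ids: {missing[:5]}")
        return idx

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.dosages, other.dosages)
            and self.variants.reset_index(drop=True).equals(
                other.variants.reset_index(drop=True)
            )
            and self.samples.reset_index(drop=True).equals(
                other.samples.reset_index(drop=True)
            )
        )


def _ext(prefix, ext: str) -> Path:
    # not Path.with_suffix: a dot in the stem must not be treated as a suffix
    prefix = Path(prefix)
    return prefix.parent / f"{prefix.name}.{ext}"


def _normalize_chrom(label) -> int:
    s = str(label).upper()
    if s in _CHROM_ALIASES:
        return _CHROM_ALIASES[s]
    try:
        return int(s)
    except ValueError as exc:
        raise PlinkError(f"unrecognized chromosome label {label!r}") from exc


def decode_bed_byte(b: int) -> list[int]:
    """Decode one .bed payload byte into four A1 dosages.

    Sample ``k`` of the byte occupies bits ``2k`` and ``2k+1`` (the first
    sample is in the least-significant pair).
    """
    return [int(_CODE_TO_DOSAGE[(b >> (2 * k)) & 0b11]) for k in range(4)]


def encode_bed_byte(dosages) -> int:
    """Inverse of :func:`decode_bed_byte` for a block of up to 4 dosages.

    Short blocks are padded with dosage 2 (code ``00``) so pad bits are zero.
    """
    b = 0
    for k in range(4):
        d = dosages[k] if k < len(dosages) else 2
        b |= int(_DOSAGE_TO_CODE[3 if d == MISSING else d]) << (2 * k)
    return b


def read_bim(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=VARIANT_COLUMNS,
        dtype={"snp": str, "a1": str, "a2": str},
    )
    df["chrom"] = df["chrom"].map(_normalize_chrom)
    df["cm"] = df["cm"].astype(float)
    df["pos"] = df["pos"].astype(int)
    return df


def read_fam(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=SAMPLE_COLUMNS,
        dtype={"fid": str, "iid": str, "father": str, "mother": str},
    )
    df["sex"] = df["sex"].astype(int)
    df["phenotype"] = df["phenotype"].astype(int)
    return df


def read_plink(prefix) -> GenotypeMatrix:
    """Read ``prefix.bed``/``.bim``/``.fam`` into a :class:`GenotypeMatrix`."""
    prefix = Path(prefix)
    paths = {ext: _ext(prefix, ext) for ext in ("bed", "bim", "fam")}
    for ext, p in paths.items():
        if not p.exists():
            raise PlinkError(f"triplet incomplete: {p} not found")
    variants = read_bim(paths["bim"])
    samples = read_fam(paths["fam"])
    n, m = len(samples), len(variants)

    raw = paths["bed"].read_bytes()
    if len(raw) < 3 or raw[:2] != _MAGIC or raw[2] != _MODE_VARIANT_MAJOR:
        raise PlinkError("unsupported bed layout (bad magic or non-variant-major mode)")
    bytes_per_variant = (n + 3) // 4
    if len(raw) != 3 + bytes_per_variant * m:
        raise PlinkError(
            f"truncated bed: expected {3 + bytes_per_variant * m} bytes, got {len(raw)}"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    blocks = payload.reshape(m, bytes_per_variant)
    # unpack 2-bit codes: four samples per byte, low pair first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts) & 0b11  # (m, bpv, 4)
    dosages = _CODE_TO_DOSAGE[codes.reshape(m, -1)[:, :n]].T  # (n, m)
    return GenotypeMatrix(np.ascontiguousarray(dosages), variants, samples)


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """Write a PLINK triplet; repeated calls are byte-identical."""
    if G.n_samples == 0:
        raise PlinkError("no samples")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    n, m = G.n_samples, G.n_variants
    bytes_per_variant = (n + 3) // 4
    d = G.dosages.T.astype(np.int64)  # (m, n)
    codes = _DOSAGE_TO_CODE[np.where(d == MISSING, 3, d)].astype(np.uint8)
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = codes  # pad code 00 -> pad bits zero
    quads = padded.reshape(m, bytes_per_variant, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (quads << shifts).sum(axis=2, dtype=np.uint16).astype(np.uint8)
    with open(_ext(prefix, "bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(bytes([_MODE_VARIANT_MAJOR]))
        fh.write(packed.tobytes())

    G.variants.to_csv(
        _ext(prefix, "bim"), sep="\t", header=False, index=False,
        columns=VARIANT_COLUMNS,
    )
    G.samples.to_csv(
        _ext(prefix, "fam"), sep="\t", header=False, index=False,
        columns=SAMPLE_COLUMNS,
    )
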