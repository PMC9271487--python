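"""Binary PLINK 1.x genotype panels.

A :class:`GenotypePanel` is the in-memory form of a PLINK .bed/.bim/.fam
trio: a samples × variants dosage matrix counting copies of allele2
(the .bim column-6 allele), with ``-1`` marking a missing call.

Only the SNP-major .bed layout (magic bytes ``6C 1B 01``) is supported;
that is the layout PLINK 1.9 has written since 2009 and the only one the
individual-level reference catalogue uses.  The 2-bit genotype codes are::

    00 -> 0 copies of allele2 (homozygous allele1)
    01 -> missing
    10 -> 1 copy  (heterozygous)
    11 -> 2 copies (homozygous allele2)

packed four samples per byte, least-significant bits first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyPanelError, FormatError

__all__ = ["VariantMeta", "GenotypePanel", "read_plink", "write_plink", "MISSING"]

#: Sentinel dosage value for a missing genotype call.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01

# byte -> 4 dosages, LSB pair first; code 01 is missing
_DECODE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _i in range(4):
        _code = (_b >> (2 * _i)) & 0b11
        _DECODE_LUT[_b, _i] = {0b00: 0, 0b01: MISSING, 0b10: 1, 0b11: 2}[_code]

_ENCODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


@dataclass(frozen=True)
class VariantMeta:
    """Annotation of one variant as carried by a .bim line."""

    rs_id: str
    chrom: str
    pos: int  # 1-based base pairs
    allele1: str
    allele2: str


@dataclass
class GenotypePanel:
    """Individual-level genotypes for a reference population.

    Parameters
    ----------
    samples
        Sample identifiers (the .fam IID column).
    variants
        Per-variant annotation, in .bim file order.
    dosages
        ``(n_samples, n_variants)`` int8 matrix of allele2 copy counts in
        {0, 1, 2}, with :data:`MISSING` (-1) for missing calls.
    """

    samples: list[str]
    variants: list[VariantMeta]
    dosages: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.samples) < 1 or len(self.variants) < 1:
            raise EmptyPanelError("a panel needs at least one sample and one variant")
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0, 1, 2} or missing (-1)")
        self._index = {v.rs_id: j for j, v in enumerate(self.variants)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, rs_id: str) -> int:
        """Column index of ``rs_id``; raises ``KeyError`` if absent."""
        return self._index[rs_id]

    def dosage_vector(self, rs_id: str) -> np.ndarray:
        """Dosage column for one variant (allele2 copies, -1 missing)."""
        return self.dosages[:, self.variant_index(rs_id)]

    def allele2_frequency(self, rs_id: str) -> float:
        """Frequency of allele2 among non-missing calls."""
        d = self.dosage_vector(rs_id)
        ok = d != MISSING
        if not ok.any():
            raise DegenerateCallsError(rs_id)
        return float(d[ok].sum()) / (2.0 * int(ok.sum()))


class DegenerateCallsError(FormatError):
    """All calls missing for a variant where a frequency was requested."""


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a binary PLINK 1.x trio ``prefix{.bed,.bim,.fam}``.

    Raises
    ------
    FileNotFoundError
        If any of the three files is absent.
    FormatError
        On a wrong magic number, individual-major layout, or a .bed file
        whose length does not match the .bim/.fam dimensions.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(prefix.suffix + ".bed")
    bim_path = prefix.with_suffix(prefix.suffix + ".bim")
    fam_path = prefix.with_suffix(prefix.suffix + ".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(p)

    samples: list[str] = []
    for line in fam_path.read_text().splitlines():
        if line.strip():
            samples.append(line.split()[1])

    variants: list[VariantMeta] = []
    for line in bim_path.read_text().splitlines():
        if not line.strip():
            continue
        chrom, rs_id, _cm, pos, a1, a2 = line.split()[:6]
        variants.append(VariantMeta(rs_id=rs_id, chrom=chrom, pos=int(pos), allele1=a1, allele2=a2))

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: not a PLINK 1.x .bed file (bad magic)")
    if raw[2] != _SNP_MAJOR:
        raise FormatError(
            f"{bed_path}: individual-major or unknown layout byte "
            f"0x{raw[2]:02X}; only SNP-major (0x01) is supported"
        )

    n, m = len(samples), len(variants)
    bytes_per_variant = (n + 3) // 4
    expected = 3 + bytes_per_variant * m
    if len(raw) != expected:
        raise FormatError(
            f"{bed_path}: {len(raw)} bytes, expected {expected} for "
            f"{n} samples x {m} variants (truncated or padded)"
        )

    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_variant)
    decoded = _DECODE_LUT[body].reshape(m, bytes_per_variant * 4)[:, :n]
    return GenotypePanel(samples=samples, variants=variants, dosages=decoded.T.copy())


def write_plink(panel: GenotypePanel, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write ``panel`` as a SNP-major binary PLINK trio.

    Returns the (.bed, .bim, .fam) paths.  ``read_plink`` applied to the
    output reproduces the panel exactly (bit-level .bed round trip).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    bed_path = prefix.with_suffix(prefix.suffix + ".bed")
    bim_path = prefix.with_suffix(prefix.suffix + ".bim")
    fam_path = prefix.with_suffix(prefix.suffix + ".fam")

    n, m = panel.n_samples, panel.n_variants
    bytes_per_variant = (n + 3) // 4
    # pad columns to a multiple of 4 samples with code 00
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    codes = np.empty_like(panel.dosages, dtype=np.uint8)
    for dose, code in _ENCODE.items():
        codes[panel.dosages == dose] = code
    padded[:, :n] = codes.T
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    ).astype(np.uint8)

    bed_path.write_bytes(_BED_MAGIC + bytes([_SNP_MAJOR]) + packed.tobytes())
    bim_path.write_text(
        "".join(
            f"{v.chrom}\t{v.rs_id}\t0\t{v.pos}\t{v.allele1}\t{v.allele2}\n"
            for v in panel.variants
        )
    )
    fam_path.write_text("".join(f"{s}\t{s}\t0\t0\t0\t-9\n" for s in panel.samples))
    return bed_path, bim_path, fam_path
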