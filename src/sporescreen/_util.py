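"""Small shared helpers: deterministic seeding, reporting arithmetic."""

from __future__ import annotations

import zlib
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

MAX_SEED = 2**31 - 1


def stable_seed(*parts) -> int:
    """Derive a reproducible child seed (< 2**31) from arbitrary parts.

    Uses crc32 over the repr of the parts so the same logical inputs give the
    same seed on every platform and run.
    """
    data = "\x1f".join(repr(p) for p in parts).encode()
    return zlib.crc32(data) & MAX_SEED


def rng_from(*parts) -> np.random.Generator:
    return np.random.default_rng(stable_seed(*parts))


def percent(numerator: int, denominator: int, digits: int = 1) -> float:
    """100*numerator/denominator rounded half-up at report precision.

    Rounding happens only here, at the report boundary; raw counts travel
    with every percentage elsewhere.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    q = Decimal(10) ** -digits
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))


RNA_COMPLEMENT = str.maketrans("ACGUNacgun", "UGCANugcan")
DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp_rna(seq: str) -> str:
    return seq.translate(RNA_COMPLEMENT)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.translate(DNA_COMPLEMENT)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")
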