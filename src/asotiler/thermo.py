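"""Melting-temperature prediction for RNA-DNA hybrid duplexes.

An antisense DNA oligo hybridized to its target RNA forms an RNA-DNA
heteroduplex, the substrate recognized by RNaseH. Duplex stability is
modeled with the nearest-neighbor method: enthalpy and entropy of duplex
formation are approximated as the sum over adjacent base-pair stacks
(dinucleotides), using the hybrid parameters of Sugimoto et al. (1995),
which are tabulated by the RNA strand read 5'->3'. The melting temperature
in degrees Celsius is

    Tm = (dH - dH_init) / (dS + R * ln(1/[oligo]) + 16.6 * log10([Na+])) - 273.15

with dH in cal/mol (the table stores kcal/mol and is converted before the
division), dS in cal/(K*mol), R the gas constant in cal/(K*mol), [oligo]
the antisense oligo concentration in mol/L (assumed in excess of the
target), [Na+] the monovalent salt concentration in mol/L, and dH_init the
helix initiation energy (-3.1 kcal/mol for RNA-DNA hybrids). The salt
term sits inside the denominator, exactly as written above; no alternative
"corrected" form is substituted.

Concentration units: the default oligo concentration is 5e-2 mol/L (the
"50 mM" reading); ``OLIGO_CONC_50NM`` provides the 5e-8 mol/L alternative
reading. Ratio-based properties (e.g. the <2 degC shift under an 8-fold
concentration change) are invariant to this choice; absolute Tm values are
not, so the value in force is carried explicitly in :class:`ThermoConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping, Tuple

__all__ = [
    "ThermoError",
    "NearestNeighborTable",
    "ThermoConfig",
    "normalize_rna",
    "stack_sums",
    "melting_temperature",
    "GAS_CONSTANT_R",
    "OLIGO_CONC_50MM",
    "OLIGO_CONC_50NM",
]

RNA_BASES = "ACGU"

#: Gas constant, cal/(K*mol). Fixed; not a tunable.
GAS_CONSTANT_R = 1.987

#: Literal reading of the default oligo concentration ("50 mM"), mol/L.
OLIGO_CONC_50MM = 5e-2
#: Alternative reading ("50 nM"), mol/L.
OLIGO_CONC_50NM = 5e-8


class ThermoError(ValueError):
    """Invalid sequence or non-physical thermodynamic parameters."""


def normalize_rna(seq: str) -> str:
    """Uppercase, map T->U, and validate the ACGU alphabet.

    Raises :class:`ThermoError` naming the 1-based position of the first
    offending character.
    """
    s = seq.upper().replace("T", "U")
    for i, c in enumerate(s):
        if c not in RNA_BASES:
            raise ThermoError(
                f"invalid RNA base {c!r} at position {i + 1} (expected A/C/G/U/T)"
            )
    return s


@dataclass(frozen=True)
class NearestNeighborTable:
    """Stack parameters keyed by RNA dinucleotide (5'->3'), one per 16 stacks.

    Values are ``(delta_H kcal/mol, delta_S cal/(K*mol))``; both are negative
    for every stack (duplex formation releases heat and orders the strands).
    """

    entries: Mapping[str, Tuple[float, float]]

    def __post_init__(self) -> None:
        expected = {a + b for a in RNA_BASES for b in RNA_BASES}
        keys = set(self.entries)
        if keys != expected:
            missing = sorted(expected - keys)
            extra = sorted(keys - expected)
            raise ThermoError(
                f"nearest-neighbor table must have exactly the 16 RNA dinucleotides; "
                f"missing={missing} unexpected={extra}"
            )
        for k, (dh, ds) in self.entries.items():
            if not (dh < 0 and ds < 0):
                raise ThermoError(f"stack {k}: delta_H and delta_S must both be negative")

    @classmethod
    def from_tsv_text(cls, text: str) -> "NearestNeighborTable":
        entries = {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ThermoError(f"nearest-neighbor TSV line {lineno}: expected 3 columns")
            dinuc, dh, ds = parts
            entries[dinuc.upper().replace("T", "U")] = (float(dh), float(ds))
        return cls(entries)

    @classmethod
    def from_tsv(cls, path) -> "NearestNeighborTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_tsv_text(fh.read())


@lru_cache(maxsize=1)
def _default_table() -> NearestNeighborTable:
    text = resources.files("asotiler.data").joinpath("rna_dna_nn.tsv").read_text("utf-8")
    return NearestNeighborTable.from_tsv_text(text)


@dataclass(frozen=True)
class ThermoConfig:
    """All constants of the Tm formula.

    Parameters
    ----------
    nn_table
        Stack enthalpies/entropies (defaults to the packaged Sugimoto 1995
        hybrid table).
    oligo_conc
        Antisense oligo concentration, mol/L. Default 5e-2 ("50 mM").
    na_conc
        Monovalent salt concentration, mol/L. Default 0.2.
    helix_init_kcal
        Helix initiation energy, kcal/mol. Default -3.1.
    """

    nn_table: NearestNeighborTable = field(default_factory=_default_table)
    oligo_conc: float = OLIGO_CONC_50MM
    na_conc: float = 0.2
    helix_init_kcal: float = -3.1

    def __post_init__(self) -> None:
        if self.oligo_conc <= 0:
            raise ThermoError("oligo_conc must be > 0 mol/L")
        if self.na_conc <= 0:
            raise ThermoError("na_conc must be > 0 mol/L")


def stack_sums(target_subseq: str, table: NearestNeighborTable | None = None) -> Tuple[float, float]:
    """Sum stack parameters over the L-1 adjacent dinucleotides of an RNA subsequence.

    Returns ``(delta_H kcal/mol, delta_S cal/(K*mol))``. The input is read
    along the target RNA 5'->3'; the antisense DNA strand never indexes the
    table (the published hybrid parameters are tabulated by the RNA strand).
    """
    if table is None:
        table = _default_table()
    s = normalize_rna(target_subseq)
    if len(s) < 2:
        raise ThermoError("need at least 2 nt to evaluate nearest-neighbor stacks")
    dh = 0.0
    ds = 0.0
    entries = table.entries
    for i in range(len(s) - 1):
        h, e = entries[s[i : i + 2]]
        dh += h
        ds += e
    return dh, ds


def melting_temperature(target_subseq: str, cfg: ThermoConfig | None = None) -> float:
    """Tm (degC) of the hybrid formed by an RNA subsequence and its antisense DNA oligo.

    Pure function of ``(sequence, cfg)``; T in the input is treated as U.
    Raises :class:`ThermoError` for a degenerate denominator (non-physical
    parameter combinations).
    """
    if cfg is None:
        cfg = ThermoConfig()
    dh_kcal, ds_cal = stack_sums(target_subseq, cfg.nn_table)
    numerator = (dh_kcal - cfg.helix_init_kcal) * 1000.0  # kcal -> cal
    denominator = (
        ds_cal
        + GAS_CONSTANT_R * math.log(1.0 / cfg.oligo_conc)
        + 16.6 * math.log10(cfg.na_conc)
    )
    if abs(denominator) < 1e-9:
        raise ThermoError("degenerate denominator in Tm formula: non-physical parameters")
    return numerator / denominator - 273.15
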