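"""Published reference measurements for E. coli GluRS and its
pZBD-chimeras, and the sequence-survey group counts.

These are measured inputs (enzyme parameters from titration/kinetics
experiments and the survey's per-group tallies); every *derived*
quantity — kcat/Km, fold changes, binding free-energy differences,
motif fractions — is recomputed from them by the functions in
:mod:`pzbd.kinetics`, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import kinetics

__all__ = [
    "VariantKinetics",
    "VARIANTS",
    "WILD_TYPE",
    "GROUP_COUNTS",
    "derived_table",
]


@dataclass(frozen=True)
class VariantKinetics:
    """Raw measured parameters for one enzyme construct (SI units)."""

    name: str
    kcat: float  # s^-1
    km: float  # M (L-glutamic acid)
    kd_atp: float  # M
    kd_trna: float  # M
    zn_ratio: float  # mol Zn / mol protein


# wild-type E. coli GluRS and the four pZBD-chimeras
VARIANTS = (
    VariantKinetics("wt", kcat=5.3, km=65.4e-6, kd_atp=28.0e-6, kd_trna=62.5e-9, zn_ratio=0.93),
    VariantKinetics("Ec(Bt)", kcat=6.6, km=139.4e-6, kd_atp=39.5e-6, kd_trna=91.0e-9, zn_ratio=0.05),
    VariantKinetics("Ec(Te)", kcat=0.20, km=250.5e-6, kd_atp=32.0e-6, kd_trna=222e-9, zn_ratio=1.08),
    VariantKinetics("Ec(EQRS)", kcat=1.5e-2, km=284.6e-6, kd_atp=35.5e-6, kd_trna=385e-9, zn_ratio=1.09),
    VariantKinetics("Ec(dH4)", kcat=8.5e-3, km=441.5e-6, kd_atp=28.0e-6, kd_trna=499e-9, zn_ratio=1.00),
)
WILD_TYPE = VARIANTS[0]

# Sequence-survey group tallies per taxon (group label -> count).
GROUP_COUNTS = {
    "bacteria-GluRS": {"I": 88, "II": 5, "III": 105, "IV": 7, "V": 7},
    "bacteria-GluQRS": {"I": 46, "II": 15},
    "archaea-GluRS": {"I": 7, "II": 16, "III": 14},
    "eukarya-GluRS": {"I": 11, "II": 1, "III": 10},
}


def derived_table(temperature: float = kinetics.STANDARD_TEMPERATURE_K):
    """Recompute every derived quantity from the raw variant parameters.

    Returns a list of per-variant dicts with catalytic efficiency,
    efficiency/kcat/Km/Kd fold changes relative to wild type, and the
    tRNA- and substrate-binding free-energy differences (kcal/mol).
    """
    wt = WILD_TYPE
    eff_wt = kinetics.efficiency(wt.kcat, wt.km)
    rows = []
    for v in VARIANTS:
        eff = kinetics.efficiency(v.kcat, v.km)
        row = {
            "name": v.name,
            "efficiency": eff,
            "activity_loss_fold": eff_wt / eff,
            "kcat_fold": wt.kcat / v.kcat,
            "km_fold": v.km / wt.km,
            "kd_trna_fold": v.kd_trna / wt.kd_trna,
            "ddg_trna_kcal": kinetics.delta_g(wt.kd_trna, v.kd_trna, temperature),
            "ddg_km_kcal": kinetics.delta_g(wt.km, v.km, temperature),
            "zn_ratio": v.zn_ratio,
        }
        rows.append(row)
    return rows
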