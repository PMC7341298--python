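"""Bundled literature values for cross-breed growth comparison.

Published Gompertz (classic-form) group means by sex for a range of
broiler hybrids and local breeds, plus actual average body weights at
selected ages.  Values are stored exactly as printed in the source
literature (hence occasional rounding inconsistencies between a table's own
rows); each entry carries a provenance note naming the breed or line and
the kind of study it came from.  Read-only: used by
:func:`flockfit.io.compare_breeds`.
"""

from __future__ import annotations

from types import MappingProxyType

__all__ = ["GOMPERTZ_CATALOG", "ACTUAL_WEIGHT_CATALOG"]

# Per-sex Gompertz parameters: bwa (g), b (-), k (1/d), bwip (g), tip (d),
# mgr (g/d) as printed in the comparison literature.
_GOMPERTZ = {
    "RS1": {
        "name": "Ross 308 (fast-growing broiler)",
        "provenance": "published review of broiler Gompertz fits",
        "F": {"bwa": 6401, "b": 4.44, "k": 0.039, "bwip": 2356, "tip": 39, "mgr": 92},
        "M": {"bwa": 6949, "b": 4.79, "k": 0.042, "bwip": 2557, "tip": 37, "mgr": 107},
    },
    "RS2": {
        "name": "Ross 708 (fast-growing broiler)",
        "provenance": "published broiler growth trial",
        "F": {"bwa": 4664, "b": 4.20, "k": 0.036, "bwip": 1716, "tip": 43, "mgr": 62},
        "M": {"bwa": 5475, "b": 4.62, "k": 0.036, "bwip": 2015, "tip": 43, "mgr": 73},
    },
    "HUB": {
        "name": "Hubbard JA57 x Redbro (medium-growing hybrid)",
        "provenance": "published hybrid growth trial",
        "F": {"bwa": 3657, "b": 4.14, "k": 0.031, "bwip": 1345, "tip": 46, "mgr": 42},
        "M": {"bwa": 4362, "b": 4.37, "k": 0.031, "bwip": 1605, "tip": 48, "mgr": 50},
    },
    "B": {
        "name": "Berlanda (slow-growing hybrid)",
        "provenance": "published slow-growing hybrid trial",
        "F": {"bwa": 2697, "b": 4.03, "k": 0.021, "bwip": 992, "tip": 69, "mgr": 21},
        "M": {"bwa": 3880, "b": 4.39, "k": 0.019, "bwip": 1427, "tip": 82, "mgr": 27},
    },
    "BS": {
        "name": "Bianca di Saluzzo (Italian slow-growing breed)",
        "provenance": "printed group-mean fits for the white Piedmont breed",
        "F": {"bwa": 2184, "b": 3.32, "k": 0.014, "bwip": 804, "tip": 86, "mgr": 11},
        "M": {"bwa": 3074, "b": 3.55, "k": 0.014, "bwip": 1131, "tip": 96, "mgr": 16},
    },
    "PA": {
        "name": "Padovana Argentata (Italian local breed)",
        "provenance": "published local-breed growth trial",
        "F": {"bwa": 2022, "b": 4.35, "k": 0.021, "bwip": 744, "tip": 75, "mgr": 16},
        "M": {"bwa": 2245, "b": 4.77, "k": 0.020, "bwip": 826, "tip": 81, "mgr": 17},
    },
    "BP": {
        "name": "Bionda Piemontese (Italian slow-growing breed)",
        "provenance": "printed group-mean fits for the blond Piedmont breed",
        "F": {"bwa": 2012, "b": 3.00, "k": 0.016, "bwip": 740, "tip": 72, "mgr": 12},
        "M": {"bwa": 2745, "b": 3.25, "k": 0.015, "bwip": 1010, "tip": 80, "mgr": 15},
    },
    "PC": {
        "name": "Padovana Camosciata (Italian local breed)",
        "provenance": "published local-breed growth trial",
        "F": {"bwa": 1979, "b": 4.01, "k": 0.020, "bwip": 728, "tip": 72, "mgr": 15},
        "M": {"bwa": 2558, "b": 4.16, "k": 0.019, "bwip": 941, "tip": 76, "mgr": 18},
    },
}

# Actual sex-averaged body weights (g) at selected ages (days), by breed code.
_ACTUAL = {
    "RS": {"name": "Ross 708", "weights": {42: 2936}},
    "SA": {"name": "SASSO", "weights": {84: 2300}},
    "RM": {"name": "Robusta Maculata", "weights": {175: 2250}},
    "ER": {"name": "Ermellinata di Rovigo", "weights": {140: 2186, 168: 2395, 190: 2900}},
    "MIL": {"name": "Milanino", "weights": {150: 2381, 180: 2541}},
    "CN": {"name": "Castellana Negra", "weights": {42: 396, 84: 1095, 140: 1812}},
    "BS": {
        "name": "Bianca di Saluzzo",
        "weights": {42: 385, 84: 1000, 140: 1623, 180: 2068, 210: 2220},
    },
    "BP": {
        "name": "Bionda Piemontese",
        "weights": {42: 448, 84: 1086, 140: 1632, 180: 2020, 210: 2147},
    },
    "BR": {"name": "Bresse", "weights": {108: 1300, 140: 1800}},
    "PD": {"name": "Padovana", "weights": {150: 1536, 180: 1800, 190: 2100}},
    "MO": {"name": "Modenese", "weights": {210: 2142}},
    "RO": {"name": "Romagnolo", "weights": {210: 2175}},
    "PE": {"name": "Pepoi", "weights": {190: 1500}},
}

GOMPERTZ_CATALOG = MappingProxyType(_GOMPERTZ)
ACTUAL_WEIGHT_CATALOG = MappingProxyType(_ACTUAL)
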