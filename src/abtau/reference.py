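"""Published reference results for this model family.

Three tables from the published description of the immunotherapy model are
distributed with the package as plain data, used to cross-check scan output
and as inputs for the rank-correlation summaries:

* ``DIRECTION_TABLE`` — the direction in which each output moves when a
  parameter is doubled (deterministic scan, day-4 passive scenario); ``None``
  means no/negligible effect on that output.
* ``PLAQUE_RANKING`` — parameters ranked by the percentage decrease in
  maximum plaque size achievable by halving or doubling them, with the
  matching soluble-Abeta ranks.
* ``TANGLE_RANKING`` — the same for maximum tangle (NFT) level, with the
  matching phospho-tau ranks (one parameter affects tangles through timing
  alone and has no phospho-tau effect; by convention it takes the lowest
  phospho-tau rank).

Also included: the measured Abeta turnover rates behind the
production/degradation ratio argument (production is identical in disease and
control; clearance is slower in disease, so the production/clearance ratio
exceeds one only in disease).
"""

from __future__ import annotations

import math

__all__ = [
    "ABETA_PRODUCTION_RATE", "ABETA_DEG_RATE_AD", "ABETA_DEG_RATE_CONTROL",
    "ANTIBODY_CLEARANCE_RATE", "production_degradation_ratio",
    "antibody_half_life_days", "DIRECTION_TABLE", "OUTPUTS",
    "PLAQUE_RANKING", "TANGLE_RANKING", "reference_rank_pairs",
]

#: measured soluble-Abeta production rate, molecules/s (same in AD & control)
ABETA_PRODUCTION_RATE = 1.86e-5
#: measured monomer clearance rates, s^-1
ABETA_DEG_RATE_AD = 1.5e-5
ABETA_DEG_RATE_CONTROL = 2.1e-5
#: antibody clearance, s^-1 (half-life about 3 days)
ANTIBODY_CLEARANCE_RATE = 2.75e-6


def production_degradation_ratio(k_deg: float,
                                 k_prod: float = ABETA_PRODUCTION_RATE) -> float:
    """Abeta production/clearance ratio; > 1 means monomers accumulate."""
    return k_prod / k_deg


def antibody_half_life_days(k_deg: float = ANTIBODY_CLEARANCE_RATE) -> float:
    return math.log(2.0) / k_deg / 86_400.0


#: scan output order used throughout
OUTPUTS = ("soluble_Abeta", "AbP", "Tau_P2", "NFT", "GliaA", "ROS")

_UP, _DN = +1, -1

#: effect of DOUBLING the parameter on each output (order as in OUTPUTS);
#: second field tags the mechanism class: DNA-damage response vs aggregation
DIRECTION_TABLE: dict[str, tuple[str, tuple[int | None, ...]]] = {
    # aggregation / intervention parameters
    "k_actglia1":        ("aggregation", (None, None, None, None, _UP, None)),
    "k_actglia2":        ("aggregation", (None, None, None, None, _UP, None)),
    "k_aggTauP2":        ("aggregation", (None, None, _DN, _UP, None, None)),
    "k_binAbantiAb":     ("aggregation", (_DN, None, _DN, _DN, _DN, _DN)),
    "k_binMTTau":        ("aggregation", (None, None, _DN, _DN, None, None)),
    "k_degAbeta":        ("aggregation", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_degAntiAb":       ("aggregation", (_UP, _UP, _UP, _UP, _DN, None)),
    "k_dephosTau":       ("aggregation", (None, None, _DN, _DN, None, None)),
    "k_dimerAbeta":      ("aggregation", (_DN, _UP, _DN, _DN, _UP, _DN)),
    "k_disaggAbP1":      ("aggregation", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_genROSPlaque":    ("aggregation", (_UP, _UP, _UP, _UP, _UP, _UP)),
    "k_inactglia1":      ("aggregation", (None, None, None, None, _DN, None)),
    "k_inactglia2":      ("aggregation", (None, None, None, None, _DN, None)),
    "k_pf":              ("aggregation", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_pg":              ("aggregation", (_UP, _UP, _UP, _UP, _UP, _UP)),
    "k_pghalf":          ("aggregation", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_phosTauGsk3bp53": ("aggregation", (None, None, _UP, _UP, None, None)),
    "k_prodAbeta2":      ("aggregation", (_UP, _UP, _UP, _UP, _UP, _UP)),
    "k_relMTTau":        ("aggregation", (None, None, _UP, _UP, None, None)),
    "k_synTau":          ("aggregation", (None, None, _UP, _UP, None, None)),
    # DNA-damage-response parameters
    "k_actATM":              ("dna-damage", (_UP, _UP, _UP, _UP, _UP, _UP)),
    "k_binGsk3bp53":         ("dna-damage", (_UP, _UP, _UP, _UP, _UP, _UP)),
    "k_binMdm2p53":          ("dna-damage", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_damROS":              ("dna-damage", (_UP, _UP, _UP, _UP, _UP, _UP)),
    "k_degMdm2mRNA":         ("dna-damage", (_UP, _UP, _UP, _UP, _UP, _UP)),
    "k_degp53mRNA":          ("dna-damage", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_dephosMdm2":          ("dna-damage", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_inactATM":            ("dna-damage", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_Mdm2Pub":             ("dna-damage", (_UP, _UP, _UP, _UP, _UP, _UP)),
    "k_phosMdm2":            ("dna-damage", (_UP, _UP, _UP, _UP, _UP, _UP)),
    "k_relGsk3bp53":         ("dna-damage", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_remROS":              ("dna-damage", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_repair":              ("dna-damage", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_synMdm2":             ("dna-damage", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_synMdm2mRNA":         ("dna-damage", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_synMdm2mRNAGsk3bp53": ("dna-damage", (_DN, _DN, _DN, _DN, _DN, _DN)),
    "k_synp53":              ("dna-damage", (_UP, _UP, _UP, _UP, _UP, _UP)),
    "k_synp53mRNA":          ("dna-damage", (_UP, _UP, _UP, _UP, _UP, _UP)),
    "k_synp53mRNAAbeta":     ("dna-damage", (_UP, _UP, _UP, _UP, _UP, _UP)),
}

#: rows: (rank, parameter, direction of change that reduces plaques
#: ("down" = halved, "up" = doubled), % decrease in max plaque, soluble-Abeta
#: rank, soluble direction, % decrease in max soluble Abeta)
PLAQUE_RANKING: list[tuple[int, str, str, float, int, str, float]] = [
    (1,  "k_prodAbeta2",          "down", 97.91, 1,  "down", 45.81),
    (2,  "k_disaggAbP1",          "up",   96.77, 23, "up",   10.11),
    (3,  "k_binGsk3bp53",         "down", 96.30, 2,  "down", 39.30),
    (4,  "k_relGsk3bp53",         "up",   96.29, 3,  "up",   39.29),
    (5,  "k_pghalf",              "up",   93.43, 24, "up",    9.42),
    (6,  "k_pg",                  "down", 57.24, 25, "down",  5.61),
    (7,  "k_synMdm2",             "up",   53.02, 5,  "up",   24.96),
    (8,  "k_degMdm2mRNA",         "down", 51.81, 6,  "down", 24.68),
    (9,  "k_binMdm2p53",          "up",   50.91, 7,  "up",   23.96),
    (10, "k_synp53",              "down", 50.46, 8,  "down", 23.60),
    (11, "k_degp53mRNA",          "up",   49.94, 11, "up",   23.49),
    (12, "k_phosMdm2",            "down", 49.15, 9,  "down", 23.58),
    (13, "k_dephosMdm2",          "up",   49.09, 10, "up",   23.56),
    (14, "k_Mdm2Pub",             "down", 48.29, 12, "down", 23.36),
    (15, "k_synp53mRNA",          "down", 41.34, 13, "down", 19.59),
    (16, "k_actATM",              "down", 39.60, 14, "down", 17.90),
    (17, "k_damROS",              "down", 39.60, 15, "down", 17.90),
    (18, "k_inactATM",            "up",   38.71, 17, "up",   17.64),
    (19, "k_degAbeta",            "up",   36.96, 16, "up",   17.66),
    (20, "k_remROS",              "up",   33.78, 19, "up",   16.06),
    (21, "k_synMdm2mRNA",         "up",   33.09, 18, "up",   16.78),
    (22, "k_genROSAbeta",         "down", 33.00, 21, "down", 11.76),
    (23, "k_pf",                  "up",   29.87, 27, "up",    2.54),
    (24, "k_repair",              "up",   24.51, 20, "up",   12.96),
    (25, "k_synMdm2mRNAGsk3bp53", "up",   22.13, 22, "up",   11.44),
    (26, "k_genROSPlaque",        "down",  5.03, 26, "down",  4.39),
    (27, "k_synp53mRNAAbeta",     "down",  3.77, 28, "down",  2.32),
    (28, "k_dimerAbeta",          "down",  3.10, 4,  "down", 28.69),
]

#: rows: (rank, parameter, direction, % decrease in max NFT, phospho-tau rank
#: (None = no phospho-tau effect), phospho-tau direction, % decrease)
TANGLE_RANKING: list[tuple[int, str, str, float, int | None, str, float]] = [
    (1,  "k_binGsk3bp53",         "down", 94.40, 1,  "down", 72.26),
    (2,  "k_relGsk3bp53",         "up",   94.40, 2,  "up",   72.25),
    (3,  "k_dephosTau",           "up",   92.65, 3,  "up",   70.60),
    (4,  "k_phosTauGsk3bp53",     "down", 92.13, 4,  "down", 69.88),
    (5,  "k_synMdm2",             "up",   80.02, 5,  "up",   54.67),
    (6,  "k_degMdm2mRNA",         "down", 79.89, 6,  "down", 54.67),
    (7,  "k_binMdm2p53",          "up",   78.66, 7,  "up",   53.33),
    (8,  "k_phosMdm2",            "down", 78.29, 8,  "down", 53.20),
    (9,  "k_dephosMdm2",          "up",   78.26, 9,  "up",   53.17),
    (10, "k_Mdm2Pub",             "down", 78.16, 10, "down", 53.16),
    (11, "k_synp53",              "down", 77.91, 11, "down", 52.49),
    (12, "k_degp53mRNA",          "up",   77.84, 12, "up",   52.49),
    (13, "k_synp53mRNA",          "down", 72.03, 13, "down", 46.72),
    (14, "k_actATM",              "down", 69.75, 16, "down", 42.23),
    (15, "k_damROS",              "down", 69.75, 17, "down", 42.23),
    (16, "k_inactATM",            "up",   69.58, 18, "up",   41.82),
    (17, "k_binMTTau",            "up",   68.72, 14, "up",   43.29),
    (18, "k_remROS",              "up",   68.55, 20, "up",   38.84),
    (19, "k_relMTTau",            "down", 68.45, 15, "down", 43.04),
    (20, "k_repair",              "up",   66.33, 22, "up",   32.45),
    (21, "k_synMdm2mRNA",         "up",   65.00, 19, "up",   41.02),
    (22, "k_genROSAbeta",         "down", 63.49, 24, "down", 26.55),
    (23, "k_prodAbeta2",          "down", 60.96, 21, "down", 33.24),
    (24, "k_synMdm2mRNAGsk3bp53", "up",   50.49, 23, "up",   29.01),
    (25, "k_aggTauP2",            "down", 47.42, 34, "down",  3.63),
    (26, "k_binAbantiAb",         "up",   47.42, 35, "up",    3.63),
    (27, "k_synTau",              "down", 28.75, 26, "down", 11.05),
    (28, "k_dimerAbeta",          "up",   25.41, 31, "up",    7.66),
    (29, "k_degAbeta",            "up",   23.76, 25, "up",   15.83),
    (30, "k_disaggAbP1",          "up",   12.31, 28, "up",    9.06),
    (31, "k_synp53mRNAAbeta",     "down", 10.67, 33, "down",  6.07),
    (32, "k_pghalf",              "up",   10.39, 29, "up",    8.92),
    (33, "k_genROSPlaque",        "down",  8.13, 27, "down", 10.51),
    (34, "k_pg",                  "down",  7.55, 30, "down",  8.72),
    (35, "k_degAntiAb",           "down",  7.41, None, "down", 0.00),
    (36, "k_pf",                  "up",    6.10, 32, "up",    6.77),
]


def reference_rank_pairs(which: str) -> tuple[list[int], list[int]]:
    """Paired (primary rank, secondary rank) columns from a reference ranking;
    a missing secondary rank takes the lowest rank (n)."""
    if which == "plaques":
        rows = [(r[0], r[4]) for r in PLAQUE_RANKING]
    elif which == "tangles":
        n = len(TANGLE_RANKING)
        rows = [(r[0], r[4] if r[4] is not None else n) for r in TANGLE_RANKING]
    else:
        raise ValueError("which must be 'plaques' or 'tangles'")
    return [a for a, _ in rows], [b for _, b in rows]
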