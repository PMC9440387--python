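"""Published F-box (Fbxw) family vs SCMC correlation coefficients.

Reference table of Pearson correlation coefficients and two-sided p-values
between mouse Fbxw-family proteins and three SCMC-side profiles (Ooep,
Nlrp5, Tle6) plus Fbxw24, computed over the six preimplantation stages
(n = 6) in three embryo proteome datasets: the uniparental/parthenogenetic
set (``PA``) and two independently published biparental sets (``ZY_Israel``,
``ZY_Gao``).  Values are as printed, rounded to four decimals; dashes in the
source (protein not detected in that dataset) are simply absent here.

These pairs serve as worked examples for the r → p transform: with n = 6,
recomputing p from the printed r reproduces the printed p at four decimals
for most cells (a handful differ by one unit in the last digit because r
itself is printed rounded).
"""

from __future__ import annotations

from .screen import CorrelationRecord, ScreenConfig, classify_strength

#: Number of stages behind each printed correlation.
FBXW_SCMC_N_STAGES = 6

# (gene, dataset, anchor, p, r)
_CELLS: list[tuple[str, str, str, float, float]] = [
    ("Fbxw8", "ZY_Israel", "Ooep", 0.5822, 0.2864),
    ("Fbxw8", "ZY_Israel", "Nlrp5", 0.6216, 0.2580),
    ("Fbxw8", "ZY_Israel", "Tle6", 0.3570, 0.4614),
    ("Fbxw8", "ZY_Israel", "Fbxw24", 0.2948, 0.5159),
    ("Fbxw8", "ZY_Gao", "Ooep", 0.0009, -0.9749),
    ("Fbxw8", "ZY_Gao", "Nlrp5", 0.0000, -0.9946),
    ("Fbxw8", "ZY_Gao", "Tle6", 0.0002, -0.9889),
    ("Fbxw8", "ZY_Gao", "Fbxw24", 0.0021, -0.9628),
    ("Fbxw11", "PA", "Ooep", 0.7422, 0.1736),
    ("Fbxw11", "PA", "Nlrp5", 0.5370, 0.3195),
    ("Fbxw11", "PA", "Tle6", 0.7132, 0.1936),
    ("Fbxw11", "ZY_Israel", "Ooep", 0.0570, -0.7981),
    ("Fbxw11", "ZY_Israel", "Nlrp5", 0.0067, -0.9325),
    ("Fbxw11", "ZY_Israel", "Tle6", 0.0287, -0.8582),
    ("Fbxw11", "ZY_Israel", "Fbxw24", 0.0502, -0.8109),
    ("Fbxw11", "ZY_Gao", "Ooep", 0.0561, -0.7997),
    ("Fbxw11", "ZY_Gao", "Nlrp5", 0.1031, -0.7250),
    ("Fbxw11", "ZY_Gao", "Tle6", 0.0924, -0.7404),
    ("Fbxw11", "ZY_Gao", "Fbxw24", 0.0346, -0.8440),
    ("Fbxw13", "ZY_Israel", "Ooep", 0.3686, 0.4517),
    ("Fbxw13", "ZY_Israel", "Nlrp5", 0.1762, 0.6342),
    ("Fbxw13", "ZY_Israel", "Tle6", 0.3035, 0.5081),
    ("Fbxw13", "ZY_Israel", "Fbxw24", 0.1168, 0.7062),
    ("Fbxw13", "ZY_Gao", "Ooep", 0.0000, 0.9949),
    ("Fbxw13", "ZY_Gao", "Nlrp5", 0.0009, 0.9755),
    ("Fbxw13", "ZY_Gao", "Tle6", 0.0004, 0.9837),
    ("Fbxw13", "ZY_Gao", "Fbxw24", 0.0002, 0.9898),
    ("Fbxw15", "PA", "Ooep", 0.0111, -0.9128),
    ("Fbxw15", "PA", "Nlrp5", 0.0247, -0.8687),
    ("Fbxw15", "PA", "Tle6", 0.0063, -0.9342),
    ("Fbxw15", "ZY_Israel", "Ooep", 0.0137, 0.9027),
    ("Fbxw15", "ZY_Israel", "Nlrp5", 0.0153, 0.8972),
    ("Fbxw15", "ZY_Israel", "Tle6", 0.0228, 0.8742),
    ("Fbxw15", "ZY_Israel", "Fbxw24", 0.0009, 0.9755),
    ("Fbxw15", "ZY_Gao", "Ooep", 0.0010, 0.9742),
    ("Fbxw15", "ZY_Gao", "Nlrp5", 0.0037, 0.9499),
    ("Fbxw15", "ZY_Gao", "Tle6", 0.0021, 0.9626),
    ("Fbxw15", "ZY_Gao", "Fbxw24", 0.0014, 0.9696),
    ("Fbxw16", "ZY_Israel", "Ooep", 0.0246, 0.8689),
    ("Fbxw16", "ZY_Israel", "Nlrp5", 0.0135, 0.9037),
    ("Fbxw16", "ZY_Israel", "Tle6", 0.0680, 0.7787),
    ("Fbxw16", "ZY_Israel", "Fbxw24", 0.0090, 0.9214),
    ("Fbxw16", "ZY_Gao", "Ooep", 0.0003, 0.9865),
    ("Fbxw16", "ZY_Gao", "Nlrp5", 0.0019, 0.9645),
    ("Fbxw16", "ZY_Gao", "Tle6", 0.0010, 0.9744),
    ("Fbxw16", "ZY_Gao", "Fbxw24", 0.0002, 0.9895),
    ("Fbxw18", "ZY_Israel", "Ooep", 0.0057, 0.9376),
    ("Fbxw18", "ZY_Israel", "Nlrp5", 0.0065, 0.9336),
    ("Fbxw18", "ZY_Israel", "Tle6", 0.0208, 0.8797),
    ("Fbxw18", "ZY_Israel", "Fbxw24", 0.0013, 0.9708),
    ("Fbxw18", "ZY_Gao", "Ooep", 0.0005, 0.9810),
    ("Fbxw18", "ZY_Gao", "Nlrp5", 0.0044, 0.9452),
    ("Fbxw18", "ZY_Gao", "Tle6", 0.0026, 0.9585),
    ("Fbxw18", "ZY_Gao", "Fbxw24", 0.0008, 0.9775),
    ("Fbxw19", "ZY_Israel", "Ooep", 0.0329, 0.8479),
    ("Fbxw19", "ZY_Israel", "Nlrp5", 0.0299, 0.8554),
    ("Fbxw19", "ZY_Israel", "Tle6", 0.0337, 0.8461),
    ("Fbxw19", "ZY_Israel", "Fbxw24", 0.0486, 0.8141),
    ("Fbxw19", "ZY_Gao", "Ooep", 0.0000, 0.9978),
    ("Fbxw19", "ZY_Gao", "Nlrp5", 0.0003, 0.9850),
    ("Fbxw19", "ZY_Gao", "Tle6", 0.0001, 0.9909),
    ("Fbxw19", "ZY_Gao", "Fbxw24", 0.0001, 0.9942),
    ("Fbxw20", "ZY_Israel", "Ooep", 0.0462, 0.8189),
    ("Fbxw20", "ZY_Israel", "Nlrp5", 0.0308, 0.8530),
    ("Fbxw20", "ZY_Israel", "Tle6", 0.0325, 0.8491),
    ("Fbxw20", "ZY_Israel", "Fbxw24", 0.0025, 0.9585),
    ("Fbxw20", "ZY_Gao", "Ooep", 0.0001, 0.9917),
    ("Fbxw20", "ZY_Gao", "Nlrp5", 0.0013, 0.9705),
    ("Fbxw20", "ZY_Gao", "Tle6", 0.0006, 0.9798),
    ("Fbxw20", "ZY_Gao", "Fbxw24", 0.0002, 0.9896),
    ("Fbxw21", "ZY_Israel", "Ooep", 0.0178, 0.8891),
    ("Fbxw21", "ZY_Israel", "Nlrp5", 0.0019, 0.9644),
    ("Fbxw21", "ZY_Israel", "Tle6", 0.0090, 0.9216),
    ("Fbxw21", "ZY_Israel", "Fbxw24", 0.0019, 0.9638),
    ("Fbxw21", "ZY_Gao", "Ooep", 0.0000, 0.9944),
    ("Fbxw21", "ZY_Gao", "Nlrp5", 0.0008, 0.9772),
    ("Fbxw21", "ZY_Gao", "Tle6", 0.0003, 0.9851),
    ("Fbxw21", "ZY_Gao", "Fbxw24", 0.0001, 0.9923),
    ("Fbxw22", "ZY_Israel", "Ooep", 0.0040, 0.9480),
    ("Fbxw22", "ZY_Israel", "Nlrp5", 0.0037, 0.9497),
    ("Fbxw22", "ZY_Israel", "Tle6", 0.0251, 0.8677),
    ("Fbxw22", "ZY_Israel", "Fbxw24", 0.0044, 0.9454),
    ("Fbxw22", "ZY_Gao", "Ooep", 0.0001, 0.9931),
    ("Fbxw22", "ZY_Gao", "Nlrp5", 0.0006, 0.9795),
    ("Fbxw22", "ZY_Gao", "Tle6", 0.0003, 0.9865),
    ("Fbxw22", "ZY_Gao", "Fbxw24", 0.0002, 0.9893),
    ("Fbxw26", "ZY_Israel", "Ooep", 0.0328, 0.8482),
    ("Fbxw26", "ZY_Israel", "Nlrp5", 0.0438, 0.8238),
    ("Fbxw26", "ZY_Israel", "Tle6", 0.0175, 0.8900),
    ("Fbxw26", "ZY_Israel", "Fbxw24", 0.0640, 0.7857),
    ("Fbxw26", "ZY_Gao", "Ooep", 0.0000, 0.9947),
    ("Fbxw26", "ZY_Gao", "Nlrp5", 0.0002, 0.9871),
    ("Fbxw26", "ZY_Gao", "Tle6", 0.0001, 0.9921),
    ("Fbxw26", "ZY_Gao", "Fbxw24", 0.0000, 0.9967),
    ("Fbxw28", "ZY_Israel", "Ooep", 0.0209, 0.8796),
    ("Fbxw28", "ZY_Israel", "Nlrp5", 0.0238, 0.8712),
    ("Fbxw28", "ZY_Israel", "Tle6", 0.0095, 0.9192),
    ("Fbxw28", "ZY_Israel", "Fbxw24", 0.0107, 0.9142),
    ("Fbxw28", "ZY_Gao", "Ooep", 0.0021, 0.9621),
    ("Fbxw28", "ZY_Gao", "Nlrp5", 0.0071, 0.9303),
    ("Fbxw28", "ZY_Gao", "Tle6", 0.0044, 0.9451),
    ("Fbxw28", "ZY_Gao", "Fbxw24", 0.0035, 0.9510),
]

#: Six cells used as worked examples for the r → p transform; all six
#: reproduce exactly at four-decimal rounding with n = 6.
WORKED_EXAMPLES: tuple[tuple[str, str, str, float, float], ...] = (
    ("Fbxw15", "PA", "Ooep", 0.0111, -0.9128),
    ("Fbxw15", "PA", "Nlrp5", 0.0247, -0.8687),
    ("Fbxw11", "ZY_Israel", "Nlrp5", 0.0067, -0.9325),
    ("Fbxw15", "ZY_Israel", "Fbxw24", 0.0009, 0.9755),
    ("Fbxw13", "ZY_Gao", "Nlrp5", 0.0009, 0.9755),
    ("Fbxw13", "ZY_Israel", "Fbxw24", 0.1168, 0.7062),
)


def fbxw_scmc_records(config: ScreenConfig | None = None) -> list[CorrelationRecord]:
    """The reference table as :class:`CorrelationRecord` objects."""
    config = config or ScreenConfig()
    return [
        CorrelationRecord(
            dataset_id=dataset,
            anchor=anchor,
            protein=gene,
            r=r,
            p=p,
            n=FBXW_SCMC_N_STAGES,
            strength=classify_strength(r, p, config),
        )
        for gene, dataset, anchor, p, r in _CELLS
    ]


__all__ = ["FBXW_SCMC_N_STAGES", "WORKED_EXAMPLES", "fbxw_scmc_records"]
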