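"""Packaged reference data: the eight silymarin parent components and the
twenty known microbial catabolites, as identified by LC-MS.

The parent list ships as the default for parent matching.  The catabolite
list parameterises the deterministic fixture in :mod:`silycat.synthetic_data`
and records, per catabolite, the observed ion, retention time, kinetic role
and relative abundance (AUC as % of the most abundant catabolite).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ParentComponent", "CataboliteRecord", "PARENT_COMPONENTS", "KNOWN_CATABOLITES"]


@dataclass(frozen=True)
class ParentComponent:
    """A silymarin constituent: flavonolignan name, [M+H]+ m/z, RT, relative %."""

    name: str
    mz: float
    rt: float
    neutral_formula: str
    relative_pct: float


#: the eight constituents of the silymarin mixture, by decreasing abundance
PARENT_COMPONENTS: tuple[ParentComponent, ...] = (
    ParentComponent("silybin B", 483.1287, 12.26, "C25H22O10", 33.4),
    ParentComponent("silybin A", 483.1288, 12.07, "C25H22O10", 19.4),
    ParentComponent("silydianin", 483.1287, 10.94, "C25H22O10", 19.2),
    ParentComponent("isosilybin A", 483.1287, 12.69, "C25H22O10", 10.2),
    ParentComponent("silychristin", 483.1287, 10.53, "C25H22O10", 9.8),
    ParentComponent("isosilybin B", 483.1287, 12.71, "C25H22O10", 8.1),
    ParentComponent("unknown flavonolignan", 483.1288, 10.29, "C25H22O10", 1.9),
    ParentComponent("2,3-dehydrosilybin", 481.1133, 10.80, "C25H20O10", 1.0),
)


@dataclass(frozen=True)
class CataboliteRecord:
    """A known silymarin catabolite and its kinetic role.

    ``relative_auc`` is the AUC of the donor-mean time course as a percentage
    of the most abundant catabolite (469.113@11.5).  ``role`` is one of
    ``transient``, ``final_early``, ``final_late``.
    """

    mz: float
    rt: float
    neutral_formula: str | None
    role: str
    relative_auc: float


#: the twenty catabolites, ordered by decreasing relative AUC.  Six are
#: transient (mid-course peak): the four hydrogenation isomers at m/z 485.144
#: plus two of the unannotated ions; the five dehydroxylation products at
#: m/z 467.098 are late finals, the remainder early finals.
KNOWN_CATABOLITES: tuple[CataboliteRecord, ...] = (
    CataboliteRecord(469.1128, 11.53, "C24H20O10", "final_early", 100.0),
    CataboliteRecord(485.1442, 11.25, "C25H24O10", "transient", 59.8),
    CataboliteRecord(485.1442, 10.36, "C25H24O10", "transient", 35.8),
    CataboliteRecord(469.1129, 11.86, "C24H20O10", "final_early", 35.7),
    CataboliteRecord(469.1128, 11.38, "C24H20O10", "final_early", 27.7),
    CataboliteRecord(469.1129, 12.01, "C24H20O10", "final_early", 21.7),
    CataboliteRecord(471.1285, 11.13, "C24H22O10", "final_early", 21.2),
    CataboliteRecord(399.1052, 10.42, "C25H18O5", "final_early", 17.4),
    CataboliteRecord(376.1391, 7.84, None, "transient", 15.7),
    CataboliteRecord(394.1496, 10.42, None, "final_early", 15.7),
    CataboliteRecord(485.1442, 11.07, "C25H24O10", "transient", 10.6),
    CataboliteRecord(469.1130, 9.78, "C24H20O10", "final_early", 9.3),
    CataboliteRecord(467.0975, 11.41, "C25H22O9", "final_late", 8.8),
    CataboliteRecord(471.1286, 9.11, "C24H22O10", "final_early", 8.1),
    CataboliteRecord(485.1442, 10.80, "C25H24O10", "transient", 6.2),
    CataboliteRecord(380.1341, 9.58, None, "transient", 5.9),
    CataboliteRecord(467.0975, 12.48, "C25H22O9", "final_late", 5.7),
    CataboliteRecord(467.0975, 13.77, "C25H22O9", "final_late", 4.3),
    CataboliteRecord(467.0975, 11.60, "C25H22O9", "final_late", 3.8),
    CataboliteRecord(467.0975, 12.24, "C25H22O9", "final_late", 1.6),
)
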