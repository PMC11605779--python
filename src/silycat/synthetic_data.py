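"""Synthetic fermentation-cohort generator.

Emulates a paired in vitro colon-fermentation study: 20 donors in two age
groups (10 healthy young, 10 healthy elder), each contributing a treatment
(silymarin) and a control well sampled at 0, 2, 4, 8 and 24 h.  The
generator produces the four tables the analysis pipeline consumes —

* an LC-MS feature matrix: 8 parent flavonolignans decaying away by 24 h,
  20 catabolites with transient / early-final / late-final kinetics, plus
  background decoy features identical across arms;
* an NMR metabolite concentration matrix (35 metabolites) with
  treatment-induced multiplicative changes per age group;
* genus- and order-level 16S count tables from a Dirichlet-multinomial with
  group-specific means and two planted age-differential genera;
* well/sample metadata.

Everything is reproducible from a single seed; each table draws from its own
seed-derived stream so adding one block never perturbs the others.  A
deterministic noise-free fixture reproducing the known parent/catabolite
tables (names, relative AUCs, 6-transient/14-final class structure) is also
provided for exact end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation import name_feature
from .kinetics import auc_trapezoid
from .reference import KNOWN_CATABOLITES, PARENT_COMPONENTS

__all__ = [
    "CohortDesign",
    "DoseSpec",
    "KineticSpec",
    "NmrEffect",
    "SimulatedCohort",
    "final_concentration",
    "parent_decay",
    "transient_course",
    "final_course",
    "default_kinetic_specs",
    "default_nmr_effects",
    "simulate_cohort",
    "build_reference_fixture",
    "write_cohort",
]


# --------------------------------------------------------------------------
# design and dose arithmetic


@dataclass(frozen=True)
class CohortDesign:
    """Paired two-arm fermentation cohort layout."""

    n_young: int = 10
    n_elder: int = 10
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 24.0)
    seed: int = 0

    @property
    def donors(self) -> list[str]:
        n = self.n_young + self.n_elder
        return [f"D{i + 1:02d}" for i in range(n)]

    def age_group(self, donor: str) -> str:
        return "young" if int(donor[1:]) <= self.n_young else "elder"


@dataclass(frozen=True)
class DoseSpec:
    """Well composition of the fermentation assay (volumes in µL)."""

    working_concentration: float = 2000.0  # µg/mL (2 mg/mL working solution)
    medium_ul: float = 835.0
    reducing_ul: float = 40.0
    fecal_ul: float = 100.0
    treatment_ul: float = 25.0


def final_concentration(dose: DoseSpec) -> float:
    """Final extract concentration in the well, µg/mL."""
    total = dose.medium_ul + dose.reducing_ul + dose.fecal_ul + dose.treatment_ul
    if total <= 0:
        raise ValueError("total well volume must be positive")
    return dose.working_concentration * dose.treatment_ul / total


# --------------------------------------------------------------------------
# kinetic primitives


def parent_decay(c0: float, k: float, t) -> np.ndarray:
    """First-order decay C0·exp(−k·t)."""
    tv = np.asarray(t, float)
    if np.any(tv < 0):
        raise ValueError("negative time")
    return c0 * np.exp(-k * tv)


def transient_course(c0: float, k1: float, k2: float, t) -> np.ndarray:
    """Bateman formation-then-decay course.

    C0·k1/(k2−k1)·(exp(−k1·t) − exp(−k2·t)); the k1 == k2 limit
    C0·k1·t·exp(−k1·t) is used when the rates coincide."""
    tv = np.asarray(t, float)
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rates must be positive")
    if np.isclose(k1, k2):
        return c0 * k1 * tv * np.exp(-k1 * tv)
    return c0 * k1 / (k2 - k1) * (np.exp(-k1 * tv) - np.exp(-k2 * tv))


def final_course(c0: float, k1: float, t, lag: float = 0.0) -> np.ndarray:
    """Saturating formation C0·(1 − exp(−k1·(t − lag)₊)); lag delays onset."""
    tv = np.maximum(np.asarray(t, float) - lag, 0.0)
    return c0 * (1.0 - np.exp(-k1 * tv))


# --------------------------------------------------------------------------
# compound and effect specifications


@dataclass(frozen=True)
class KineticSpec:
    """Kinetic model of one LC-MS compound in treatment wells.

    ``role``: parent | transient | final_early | final_late | decoy.
    ``amplitude`` sets the intensity scale (and hence the AUC); ``k1`` is the
    decay rate for parents and the formation rate otherwise; ``k2`` the
    downstream decay of transients; ``lag`` (h) delays late catabolites.
    ``group_multiplier`` scales the elder group's formation amplitude, i.e.
    acts directly on the AUC.  ``coupled_taxon`` ties the donor's formation
    amplitude to that taxon's clr abundance with target correlation
    ``coupling_r``.
    """

    feature_id: str
    mz: float
    rt: float
    role: str
    amplitude: float
    k1: float = 0.35
    k2: float = 0.0
    lag: float = 0.0
    group_multiplier: float = 1.0
    coupled_taxon: str | None = None
    coupling_r: float = 0.8

    def course(self, t) -> np.ndarray:
        if self.role == "parent":
            return parent_decay(self.amplitude, self.k1, t)
        if self.role == "transient":
            return transient_course(self.amplitude, self.k1, self.k2, t)
        if self.role in ("final_early", "final_late"):
            return final_course(self.amplitude, self.k1, t, self.lag)
        if self.role == "decoy":
            return np.full(len(np.asarray(t)), self.amplitude, float)
        raise ValueError(f"unknown role {self.role!r}")


_ROLE_RATES = {
    # role -> (k1, k2, lag): parents decay fully by 24 h; transients peak at
    # ~4 h; early finals are detectable from 2 h; late finals rise after 8 h
    "parent": (0.30, 0.0, 0.0),
    "parent_fast": (0.80, 0.0, 0.0),  # silychristin, 2,3-dehydrosilybin: gone by 8 h
    "transient": (0.50, 0.15, 0.0),
    "final_early": (0.35, 0.0, 0.0),
    "final_late": (0.25, 0.0, 6.0),
}

_FAST_PARENTS = ("silychristin", "2,3-dehydrosilybin")


#: planted age-group structure: the 399.105@10.4 catabolite (C08) is produced
#: 2.5-fold more by elder microbiota and its formation tracks Oscillibacter
#: abundance; isosilybin B (P6) degrades more slowly in elders (higher AUC)
_ELDER_CATABOLITE = "C08"
_ELDER_CATABOLITE_FOLD = 2.5
_ELDER_CATABOLITE_TAXON = "Oscillibacter"
_SLOW_ELDER_PARENT = "P6"
_SLOW_ELDER_PARENT_FOLD = 1.3


def default_kinetic_specs(n_decoys: int = 10) -> list[KineticSpec]:
    """Packaged compound roster: the 8 parents, the 20 known catabolites with
    their kinetic roles and relative abundances, the planted age-group
    structure, and background decoys."""
    specs: list[KineticSpec] = []
    for i, p in enumerate(PARENT_COMPONENTS):
        kind = "parent_fast" if p.name in _FAST_PARENTS else "parent"
        k1, k2, lag = _ROLE_RATES[kind]
        fid = f"P{i + 1}"
        specs.append(
            KineticSpec(
                feature_id=fid,
                mz=p.mz,
                rt=p.rt,
                role="parent",
                amplitude=100.0 * p.relative_pct,
                k1=k1,
                k2=k2,
                lag=lag,
                group_multiplier=(
                    _SLOW_ELDER_PARENT_FOLD if fid == _SLOW_ELDER_PARENT else 1.0
                ),
            )
        )
    for i, c in enumerate(KNOWN_CATABOLITES):
        k1, k2, lag = _ROLE_RATES[c.role]
        fid = f"C{i + 1:02d}"
        elder_target = fid == _ELDER_CATABOLITE
        specs.append(
            KineticSpec(
                feature_id=fid,
                mz=c.mz,
                rt=c.rt,
                role=c.role,
                amplitude=50.0 * c.relative_auc,
                k1=k1,
                k2=k2,
                lag=lag,
                group_multiplier=_ELDER_CATABOLITE_FOLD if elder_target else 1.0,
                coupled_taxon=_ELDER_CATABOLITE_TAXON if elder_target else None,
            )
        )
    for i in range(n_decoys):
        specs.append(
            KineticSpec(
                feature_id=f"X{i + 1}",
                mz=150.0 + 17.3 * i,
                rt=2.0 + 0.9 * i,
                role="decoy",
                amplitude=800.0,
            )
        )
    return specs


@dataclass(frozen=True)
class NmrEffect:
    """Multiplicative treatment effect (%) on one metabolite's AUC, per group."""

    metabolite: str
    young_pct: float = 0.0
    elder_pct: float = 0.0


#: treatment effect sizes (relative change %, young / elder) of the 14
#: responsive metabolites; the remaining 21 quantified metabolites are null
_RESPONSIVE_EFFECTS: tuple[tuple[str, float, float], ...] = (
    ("acetate", -2.02, -2.66),
    ("butyrate", -2.66, -3.44),
    ("glucose", 12.16, 8.79),
    ("isobutyrate", -6.77, -9.61),
    ("isoleucine", 1.30, 4.72),
    ("isovalerate", -6.16, -11.41),
    ("leucine", 0.71, 4.45),
    ("phenylacetic acid", -3.94, -8.53),
    ("phenylalanine", 1.34, 4.28),
    ("propionate", -3.02, -3.07),
    ("trehalose", 6.26, 3.38),
    ("tryptophan", 8.17, 9.64),
    ("valerate", -2.09, -6.35),
    ("valine", 3.91, 3.22),
)

_NULL_METABOLITES: tuple[str, ...] = (
    "lactate", "succinate", "formate", "ethanol", "methanol", "glycerol",
    "alanine", "glycine", "threonine", "lysine", "tyrosine", "aspartate",
    "glutamate", "uracil", "hypoxanthine", "maltose", "galactose",
    "fumarate", "pyruvate", "choline", "trimethylamine",
)

#: metabolites consumed over the incubation (declining control course);
#: everything else is produced or stable
_CONSUMED = {"glucose", "maltose", "trehalose", "galactose"}


def default_nmr_effects() -> list[NmrEffect]:
    effects = [NmrEffect(m, y, e) for m, y, e in _RESPONSIVE_EFFECTS]
    effects += [NmrEffect(m) for m in _NULL_METABOLITES]
    return effects


@dataclass(frozen=True)
class TaxaSpec:
    """Dirichlet-multinomial community model.

    40 genera mapped onto 12 orders; two genera carry a two-fold group
    difference in mean relative abundance (one young-high, one elder-high).
    Treatment slightly flattens the 24 h mean composition (evenness increase).
    """

    n_genera: int = 40
    n_orders: int = 12
    depth: int = 50_000
    concentration: float = 200.0
    abundance_log_sd: float = 1.6  # skew of the mean composition
    young_high_genus: str = "Faecalibacterium"
    elder_high_genus: str = "Oscillibacter"
    group_fold: float = 2.0
    treatment_evenness: float = 0.05

    def genera(self) -> list[str]:
        names = [self.young_high_genus, self.elder_high_genus]
        names += [f"genus_{i + 1:02d}" for i in range(self.n_genera - 2)]
        return names

    def taxonomy(self) -> dict[str, str]:
        # blocked assignment: consecutive (abundance-ranked) genera share an
        # order, giving the skewed order-level profile real communities show
        return {
            g: f"order_{int(i * self.n_orders / self.n_genera) + 1:02d}"
            for i, g in enumerate(self.genera())
        }


# --------------------------------------------------------------------------
# the cohort simulator


@dataclass
class SimulatedCohort:
    """Bundle of generated tables plus the ground truth that produced them."""

    design: CohortDesign
    features: pd.DataFrame  # feature id x (mz, rt, wells)
    meta: pd.DataFrame  # well x (donor, age_group, arm, timepoint)
    metabolites: pd.DataFrame  # metabolite x wells
    taxa_genus: pd.DataFrame  # genus x 16S samples
    taxa_order: pd.DataFrame
    taxa_meta: pd.DataFrame  # 16S sample x (donor, age_group, arm, timepoint)
    kinetic_specs: list[KineticSpec] = field(default_factory=list)
    nmr_effects: list[NmrEffect] = field(default_factory=list)
    taxonomy: dict = field(default_factory=dict)


def _well(donor: str, arm: str, t: float) -> str:
    return f"{donor}_{arm}_{t:g}"


def _well_meta(design: CohortDesign) -> pd.DataFrame:
    rows = []
    for donor in design.donors:
        for arm in ("treatment", "control"):
            for t in design.timepoints:
                rows.append(
                    {
                        "well": _well(donor, arm, t),
                        "donor": donor,
                        "age_group": design.age_group(donor),
                        "arm": arm,
                        "timepoint": t,
                    }
                )
    return pd.DataFrame(rows).set_index("well")


def simulate_cohort(
    design: CohortDesign,
    kinetic_specs: list[KineticSpec] | None = None,
    nmr_effects: list[NmrEffect] | None = None,
    taxa_spec: TaxaSpec | None = None,
    donor_amplitude_sd: float = 0.15,
    donor_rate_sd: float = 0.10,
    intensity_cv: float = 0.20,
    nmr_noise_sd: float = 0.02,
    nmr_effect_sd: float = 0.04,
) -> SimulatedCohort:
    """Generate a full paired fermentation cohort.

    Control wells carry no silymarin signal (parents and catabolites exactly
    zero before noise, and multiplicative noise keeps them zero); treatment
    wells follow each compound's kinetic model with donor-level lognormal
    variation on amplitude (sd ``donor_amplitude_sd``) and rates
    (``donor_rate_sd``), elder-group multipliers on amplitude, and
    well-level multiplicative lognormal intensity noise (CV ``intensity_cv``).
    Taxon couplings act on the *within-group* clr deviation, so they create
    donor-level correlation without confounding the group multiplier.
    NMR concentrations get per-group multiplicative treatment effects with
    donor-level heterogeneity (sd ``nmr_effect_sd`` on the relative-change
    scale) and multiplicative noise of log-sd ``nmr_noise_sd``.  The output
    is a pure function of the design (including its seed) and the specs.
    """
    specs = default_kinetic_specs() if kinetic_specs is None else kinetic_specs
    effects = default_nmr_effects() if nmr_effects is None else nmr_effects
    tspec = TaxaSpec() if taxa_spec is None else taxa_spec

    ss = np.random.SeedSequence(design.seed)
    rng_donor, rng_feat, rng_nmr, rng_taxa = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    donors = design.donors
    t = np.asarray(design.timepoints, float)
    meta = _well_meta(design)

    # ---- taxa first: catabolite couplings may read clr abundances
    genera = tspec.genera()
    taxonomy = tspec.taxonomy()
    base_alpha = np.sort(
        rng_taxa.lognormal(0.0, tspec.abundance_log_sd, size=tspec.n_genera)
    )[::-1]
    base_alpha /= base_alpha.sum()
    idx_young = genera.index(tspec.young_high_genus)
    idx_elder = genera.index(tspec.elder_high_genus)

    taxa_cols, taxa_rows, clr_treatment_24 = {}, [], {}
    for donor in donors:
        group = design.age_group(donor)
        mean = base_alpha.copy()
        if group == "young":
            mean[idx_young] *= tspec.group_fold
        else:
            mean[idx_elder] *= tspec.group_fold
        mean /= mean.sum()
        for arm in ("treatment", "control"):
            for tp in (0.0, 24.0):
                m = mean
                if arm == "treatment" and tp == 24.0 and tspec.treatment_evenness > 0:
                    m = mean ** (1.0 - tspec.treatment_evenness)
                    m = m / m.sum()
                p = rng_taxa.dirichlet(m * tspec.concentration)
                counts = rng_taxa.multinomial(tspec.depth, p)
                sample = _well(donor, arm, tp)
                taxa_cols[sample] = counts
                taxa_rows.append(
                    {
                        "sample": sample,
                        "donor": donor,
                        "age_group": group,
                        "arm": arm,
                        "timepoint": tp,
                    }
                )
                if arm == "treatment" and tp == 24.0:
                    logc = np.log(counts + 1.0)
                    clr_treatment_24[donor] = logc - logc.mean()

    taxa_genus = pd.DataFrame(taxa_cols, index=genera)
    taxa_order = taxa_genus.groupby([taxonomy[g] for g in genera]).sum()
    taxa_meta = pd.DataFrame(taxa_rows).set_index("sample")

    # ---- donor-level kinetic variability
    amp_factor = {
        (d, s.feature_id): float(rng_donor.lognormal(0.0, donor_amplitude_sd))
        for d in donors
        for s in specs
        if s.role != "decoy"
    }
    rate_factor = {
        (d, s.feature_id): float(rng_donor.lognormal(0.0, donor_rate_sd))
        for d in donors
        for s in specs
        if s.role != "decoy"
    }

    # clr of each coupled taxon, standardized within each age group so the
    # coupling drives donor-level correlation without touching group means
    coupled_taxa = {s.coupled_taxon for s in specs if s.coupled_taxon}
    taxon_z: dict = {}
    for taxon in coupled_taxa:
        if taxon not in genera:
            raise ValueError(f"coupling refers to unknown taxon {taxon!r}")
        gi = genera.index(taxon)
        z = {}
        for grp in ("young", "elder"):
            members = [d for d in donors if design.age_group(d) == grp]
            vals = np.array([clr_treatment_24[d][gi] for d in members])
            sd = vals.std() or 1.0
            z.update(dict(zip(members, (vals - vals.mean()) / sd)))
        taxon_z[taxon] = z

    # residual donor-level spread of log AUC, used to size the coupling slope
    sigma_rest = float(np.hypot(donor_amplitude_sd, 0.6 * intensity_cv))

    feat_rows = {}
    for spec in specs:
        row = {"mz": spec.mz, "rt": spec.rt}
        for donor in donors:
            group = design.age_group(donor)
            if spec.role == "decoy":
                # matrix background: identical in the paired wells of a donor
                level = spec.amplitude * rng_feat.lognormal(0.0, intensity_cv)
                noise = rng_feat.lognormal(0.0, intensity_cv, size=t.size)
                course = np.full(t.size, level) * noise
                for arm in ("treatment", "control"):
                    for j, tp in enumerate(t):
                        row[_well(donor, arm, tp)] = course[j]
                continue
            amp = spec.amplitude * amp_factor[(donor, spec.feature_id)]
            if group == "elder":
                amp *= spec.group_multiplier
            if spec.coupled_taxon:
                r = spec.coupling_r
                beta = r / np.sqrt(max(1.0 - r * r, 1e-9)) * sigma_rest
                amp *= float(np.exp(beta * taxon_z[spec.coupled_taxon][donor]))
            rf = rate_factor[(donor, spec.feature_id)]
            donor_spec = replace(spec, amplitude=amp, k1=spec.k1 * rf,
                                 k2=spec.k2 * rf if spec.k2 else spec.k2)
            course = donor_spec.course(t)
            sigma = float(np.sqrt(np.log1p(intensity_cv**2)))
            noisy = course * rng_feat.lognormal(0.0, sigma, size=t.size)
            for j, tp in enumerate(t):
                row[_well(donor, "treatment", tp)] = noisy[j]
                row[_well(donor, "control", tp)] = 0.0
        feat_rows[spec.feature_id] = row
    features = pd.DataFrame.from_dict(feat_rows, orient="index")
    features.index.name = "feature_id"

    # ---- NMR metabolome
    met_rows = {}
    for eff in effects:
        base_level = float(rng_nmr.lognormal(0.5, 0.5))  # mM scale
        trend = -0.6 if eff.metabolite in _CONSUMED else float(rng_nmr.uniform(0.2, 1.0))
        shape = np.clip(1.0 + trend * t / 24.0, 0.05, None)
        row = {}
        for donor in donors:
            group = design.age_group(donor)
            delta = (eff.young_pct if group == "young" else eff.elder_pct) / 100.0
            # donors respond heterogeneously around the group-level effect
            delta_d = delta + rng_nmr.normal(0.0, nmr_effect_sd)
            donor_base = base_level * rng_nmr.lognormal(0.0, 0.3)
            ctrl = donor_base * shape * rng_nmr.lognormal(0.0, nmr_noise_sd, t.size)
            trt = (
                donor_base
                * shape
                * max(1.0 + delta_d, 0.05)
                * rng_nmr.lognormal(0.0, nmr_noise_sd, t.size)
            )
            for j, tp in enumerate(t):
                row[_well(donor, "control", tp)] = ctrl[j]
                row[_well(donor, "treatment", tp)] = trt[j]
        met_rows[eff.metabolite] = row
    metabolites = pd.DataFrame.from_dict(met_rows, orient="index")
    metabolites.index.name = "metabolite"

    return SimulatedCohort(
        design=design,
        features=features,
        meta=meta,
        metabolites=metabolites,
        taxa_genus=taxa_genus,
        taxa_order=taxa_order,
        taxa_meta=taxa_meta,
        kinetic_specs=specs,
        nmr_effects=effects,
        taxonomy=taxonomy,
    )


# --------------------------------------------------------------------------
# deterministic fixture


_FIXTURE_SHAPES = {
    # unit shapes on the (0, 2, 4, 8, 24) h grid; scaling preserves class
    "parent": np.array([1.0, 0.65, 0.40, 0.15, 0.0]),
    "parent_fast": np.array([1.0, 0.50, 0.15, 0.0, 0.0]),
    "transient": np.array([0.0, 0.40, 1.00, 0.50, 0.0]),
    "final_early": np.array([0.0, 0.20, 0.50, 0.80, 1.0]),
    "final_late": np.array([0.0, 0.0, 0.0, 0.30, 1.0]),
}

_FIXTURE_TOP_AUC = 1000.0  # a.u.·h for the most abundant catabolite


@dataclass
class ReferenceFixture:
    """Deterministic, noise-free dataset for exact end-to-end checks."""

    features: pd.DataFrame
    meta: pd.DataFrame
    parent_ids: list[str]
    catabolite_ids: list[str]
    decoy_ids: list[str]
    expected_names: dict[str, str]  # catabolite feature id -> "m/z@RT" name
    expected_relative_auc: dict[str, float]
    expected_class: dict[str, str]


def build_reference_fixture(n_decoys: int = 5) -> ReferenceFixture:
    """Noise-free cohort whose analysis reproduces the known catabolite table.

    All 20 donors share each compound's time-course shape; donor d gets a
    small deterministic scale factor (1 + 0.002·d) on treatment intensities,
    which unties the signed-rank differences without touching relative AUCs
    (the common mean factor cancels).  Catabolite amplitudes are scaled so
    the donor-mean AUCs equal the published relative-AUC column exactly, and
    the class shapes realise 6 transient / 14 final (9 early, 5 late)
    kinetics.  Decoy features are identical across arms, so the treatment
    filter removes exactly them.
    """
    design = CohortDesign()
    t = np.asarray(design.timepoints, float)
    meta = _well_meta(design)

    compounds = []  # (feature_id, mz, rt, course)
    parent_ids, catabolite_ids, decoy_ids = [], [], []
    expected_names, expected_rel, expected_cls = {}, {}, {}

    for i, p in enumerate(PARENT_COMPONENTS):
        fid = f"P{i + 1}"
        kind = "parent_fast" if p.name in _FAST_PARENTS else "parent"
        course = _FIXTURE_SHAPES[kind] * (100.0 * p.relative_pct)
        compounds.append((fid, p.mz, p.rt, course))
        parent_ids.append(fid)

    for i, c in enumerate(KNOWN_CATABOLITES):
        fid = f"C{i + 1:02d}"
        shape = _FIXTURE_SHAPES[c.role]
        target_auc = c.relative_auc / 100.0 * _FIXTURE_TOP_AUC
        course = shape * (target_auc / auc_trapezoid(t, shape))
        compounds.append((fid, c.mz, c.rt, course))
        catabolite_ids.append(fid)
        expected_names[fid] = name_feature(c.mz, c.rt)
        expected_rel[fid] = c.relative_auc
        expected_cls[fid] = c.role

    rows = {}
    donors = design.donors
    for fid, mz, rt, course in compounds:
        row = {"mz": mz, "rt": rt}
        for d, donor in enumerate(donors):
            scale = 1.0 + 0.002 * d
            for j, tp in enumerate(t):
                row[_well(donor, "treatment", tp)] = course[j] * scale
                row[_well(donor, "control", tp)] = 0.0
        rows[fid] = row

    for i in range(n_decoys):
        fid = f"X{i + 1}"
        row = {"mz": 200.0 + 23.7 * i, "rt": 3.0 + 1.1 * i}
        for donor in donors:
            for tp in t:
                row[_well(donor, "treatment", tp)] = 500.0
                row[_well(donor, "control", tp)] = 500.0
        rows[fid] = row
        decoy_ids.append(fid)

    features = pd.DataFrame.from_dict(rows, orient="index")
    features.index.name = "feature_id"
    return ReferenceFixture(
        features=features,
        meta=meta,
        parent_ids=parent_ids,
        catabolite_ids=catabolite_ids,
        decoy_ids=decoy_ids,
        expected_names=expected_names,
        expected_relative_auc=expected_rel,
        expected_class=expected_cls,
    )


# --------------------------------------------------------------------------
# I/O


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write the four tables (plus taxa metadata) as TSV; returns the paths."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": out / "features.tsv",
        "meta": out / "meta.tsv",
        "metabolites": out / "metabolites.tsv",
        "taxa_genus": out / "taxa_genus.tsv",
        "taxa_order": out / "taxa_order.tsv",
        "taxa_meta": out / "taxa_meta.tsv",
    }
    cohort.features.to_csv(paths["features"], sep="\t")
    cohort.meta.to_csv(paths["meta"], sep="\t")
    cohort.metabolites.to_csv(paths["metabolites"], sep="\t")
    cohort.taxa_genus.to_csv(paths["taxa_genus"], sep="\t")
    cohort.taxa_order.to_csv(paths["taxa_order"], sep="\t")
    cohort.taxa_meta.to_csv(paths["taxa_meta"], sep="\t")
    return {k: str(v) for k, v in paths.items()}
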