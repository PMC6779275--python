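"""Model constants, units and configuration handling.

All concentrations are expressed in nM, times in minutes.  Bimolecular rate
constants are given in nM^-1 min^-1 and are converted to per-copy propensity
factors (min^-1 per molecule) by dividing by ``N_A * V * 1e-9`` — the number of
copies per nM for the configured cell volume.  Molecule counts are integers.

The default configuration shipped with the package encodes the study
conditions: HeLa receptor surface counts (TNFR1 905, DR4 769, DR5 926), a mean
XIAP level of 63 nM, an XIAP-driven Casp3 ubiquitination/degradation constant
of 1.75 min^-1 against a basal ubiquitin-dependent degradation of 0.04 min^-1.
Rate constants and initial concentrations that are not printed in the primary
sources are calibrated placeholders and are flagged as such in the config
metadata (``placeholder: true``).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, fields as dc_fields, asdict
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

AVOGADRO = 6.02214076e23

__all__ = [
    "AVOGADRO",
    "ConfigError",
    "MissingKeyError",
    "UnknownKeyError",
    "ValidationError",
    "CellGeometry",
    "InitialConcentrations",
    "KineticParameters",
    "SubunitMasses",
    "ReceptorSpec",
    "ClusteringConfig",
    "SimulationConfig",
    "ModelConfig",
    "concentration_to_copies",
    "copies_to_concentration",
    "ligand_dose_to_nm",
    "load_model_config",
    "default_config",
]


class ConfigError(Exception):
    """Base class for configuration errors; ``code`` identifies the failure."""

    code = "config_error"


class MissingKeyError(ConfigError):
    code = "missing_key"

    def __init__(self, section: str, key: str):
        self.section = section
        self.key = key
        super().__init__(f"missing required key '{key}' in section '{section}'")


class UnknownKeyError(ConfigError):
    code = "unknown_key"

    def __init__(self, section: str, key: str):
        super().__init__(f"unknown key '{key}' in section '{section}'")


class ValidationError(ConfigError):
    code = "validation_error"


@dataclass(frozen=True)
class CellGeometry:
    """Cell volume used for nM <-> copy-number conversion.

    The default of 2.5e-12 L is a typical HeLa cytosolic volume; it is a
    configurable model input, reported in all output metadata.
    """

    volume_l: float = 2.5e-12
    avogadro: float = AVOGADRO

    def __post_init__(self):
        if self.volume_l <= 0:
            raise ValidationError(f"cell volume must be > 0, got {self.volume_l}")

    @property
    def copies_per_nm(self) -> float:
        """Molecule copies corresponding to 1 nM in this volume."""
        return 1e-9 * self.avogadro * self.volume_l


def concentration_to_copies(c_nm: float, geom: CellGeometry) -> int:
    """Convert a concentration in nM to an integer per-cell molecule count."""
    if c_nm < 0:
        raise ValidationError(f"concentration must be >= 0, got {c_nm}")
    return int(round(c_nm * geom.copies_per_nm))


def copies_to_concentration(n: float, geom: CellGeometry) -> float:
    """Convert a per-cell molecule count to nM."""
    if n < 0:
        raise ValidationError(f"copy number must be >= 0, got {n}")
    return n / geom.copies_per_nm


def ligand_dose_to_nm(dose_ng_ml: float, monomer_mass_kda: float) -> float:
    """Convert a ligand dose in ng/mL to nM of ligand monomer.

    ng/mL == ug/L; dividing by the monomer mass in kDa (== ug/nmol) gives
    nmol/L == nM.
    """
    if dose_ng_ml < 0:
        raise ValidationError(f"ligand dose must be >= 0, got {dose_ng_ml}")
    if monomer_mass_kda <= 0:
        raise ValidationError("ligand monomer mass must be > 0")
    return dose_ng_ml / monomer_mass_kda


def _check_nonneg(obj, names):
    for name in names:
        v = getattr(obj, name)
        if v < 0:
            raise ValidationError(f"'{name}' must be >= 0, got {v}")


@dataclass(frozen=True)
class InitialConcentrations:
    """Starting cytosolic protein levels in nM."""

    fadd: float = 50.0
    rip1: float = 60.0
    rip3: float = 8.0
    procasp8: float = 90.0
    cflip_l: float = 20.0
    cflip_s: float = 10.0
    procasp3: float = 200.0
    procasp6: float = 60.0
    xiap: float = 63.0
    fret_substrate: float = 600.0

    def __post_init__(self):
        _check_nonneg(self, [f.name for f in dc_fields(self)])


@dataclass(frozen=True)
class KineticParameters:
    """Association (nM^-1 min^-1), dissociation and catalytic (min^-1) rates.

    Platform assembly
    -----------------
    kon_rip1_rip1        RHIM-mediated RIP1 filament elongation, per filament end
    kon_rip3_rip1        RIP3 recruitment, per bound RIP1 subunit
    kon_fadd_platform    FADD binding, per platform (filament interface)
    kon_*_ded            ProCasp8 / cFLIPl / cFLIPs / free DED1-DED2 binding to
                         a FADD-exposed DED site (also used for filament-end
                         blocking events)
    k_cis_dimer          cis-dimerization per pair of platform-bound ProCasp8
    k_trans_dimer        trans-dimerization per cross-origin pair inside one
                         receptor cluster
    k_dimer_diss         dissociation of an intact platform dimer
    k_casp8_activation   cleavage/activation of a formed dimer (releases one
                         active Casp8 dimer + one DED1-DED2 to the cytosol)

    Caspase cascade
    ---------------
    k_casp8_casp3        Casp8-dimer-catalysed ProCasp3 -> Casp3*
    k_casp3_auto         Casp3* autocatalysis on ProCasp3
    k_casp3_casp6        Casp3*-catalysed ProCasp6 -> Casp6*
    k_casp6_casp8        Casp6*-catalysed cleavage of free ProCasp8
    k_casp8m_dimerization  slow second-order dimerization of cleaved monomers
    k_casp8m_deg         turnover of the cleaved Casp8 monomer
    k_casp8d_diss        cytosolic active-dimer dissociation back to monomers
    kon_xiap_casp3 / koff_xiap_casp3  reversible XIAP.Casp3 binding
    kcat_ub              XIAP-driven Casp3 ubiquitination/degradation, 1.75 min^-1
    k_basal_deg          basal ubiquitin-dependent degradation, 0.04 min^-1
    k_fret_cleavage      Casp8-dimer-specific FRET substrate cleavage
    """

    # assembly, bimolecular (nM^-1 min^-1)
    kon_rip1_rip1: float = 0.05
    kon_rip3_rip1: float = 1.0e-5
    kon_fadd_platform: float = 1.0e-2
    kon_procasp8_ded: float = 1.5e-3
    kon_cflip_l_ded: float = 7.5e-4
    kon_cflip_s_ded: float = 7.5e-4
    kon_ded12_ded: float = 7.5e-4
    # assembly, unimolecular (min^-1)
    koff_rip1_rip1: float = 1.0e-4
    koff_rip3_rip1: float = 0.01
    koff_fadd_platform: float = 0.12
    koff_procasp8_ded: float = 0.3
    koff_cflip_l_ded: float = 0.3
    koff_cflip_s_ded: float = 0.3
    koff_ded12_ded: float = 0.3
    k_cis_dimer: float = 0.006
    k_trans_dimer: float = 0.0015
    k_dimer_diss: float = 0.2
    k_casp8_activation: float = 1.0
    # cascade
    k_casp8_casp3: float = 0.02
    k_casp3_auto: float = 0.06
    k_casp3_casp6: float = 0.01
    k_casp6_casp8: float = 1.0e-4
    k_casp8m_dimerization: float = 1.0e-4
    k_casp8m_deg: float = 0.01
    k_casp8d_diss: float = 0.1
    kon_xiap_casp3: float = 0.3
    koff_xiap_casp3: float = 0.05
    kcat_ub: float = 1.75
    k_basal_deg: float = 0.04
    k_fret_cleavage: float = 0.0025
    # fraction of k_casp8_activation retained by a ProCasp8-cFLIPl
    # heterodimer (0 = catalytically dead; literature is divided)
    cflipl_heterodimer_activity: float = 0.0
    # fraction of XIAP returned to the free pool when its Casp3 cargo is
    # degraded (1 = catalytic inhibitor cycle, 0 = XIAP consumed)
    xiap_recycled: float = 0.5

    def __post_init__(self):
        _check_nonneg(self, [f.name for f in dc_fields(self)])
        if self.kcat_ub <= self.k_basal_deg:
            raise ValidationError(
                "kcat_ub must exceed k_basal_deg "
                f"({self.kcat_ub} <= {self.k_basal_deg})"
            )
        if not 0.0 <= self.xiap_recycled <= 1.0:
            raise ValidationError("xiap_recycled must lie in [0, 1]")


@dataclass(frozen=True)
class SubunitMasses:
    """Subunit masses in kDa (canonical UniProt values by default)."""

    rip1: float = 76.0
    rip3: float = 57.0
    fadd: float = 23.0
    procasp8: float = 55.0
    cflip_l: float = 55.0
    cflip_s: float = 26.0
    ded12: float = 26.0

    def __post_init__(self):
        for f in dc_fields(self):
            if getattr(self, f.name) <= 0:
                raise ValidationError(f"mass '{f.name}' must be > 0")


@dataclass(frozen=True)
class ReceptorSpec:
    """One death-receptor species: surface count and ligand affinity."""

    count: int
    kd_nm: float

    def __post_init__(self):
        if self.count < 0 or int(self.count) != self.count:
            raise ValidationError(f"receptor count must be a nonneg integer, got {self.count}")
        if self.kd_nm <= 0:
            raise ValidationError(f"Kd must be > 0, got {self.kd_nm}")


@dataclass(frozen=True)
class ClusteringConfig:
    """Receptor cluster-size distribution (sizes in trimer units)."""

    sizes: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 12, 16, 20)
    probabilities: tuple = (0.38, 0.19, 0.12, 0.085, 0.065, 0.045, 0.03, 0.02,
                            0.03, 0.02, 0.015)

    def __post_init__(self):
        if len(self.sizes) != len(self.probabilities):
            raise ValidationError("cluster sizes and probabilities differ in length")
        if any(s < 1 or int(s) != s for s in self.sizes):
            raise ValidationError("cluster sizes must be integers >= 1")
        if any(p < 0 for p in self.probabilities):
            raise ValidationError("cluster probabilities must be >= 0")
        if abs(sum(self.probabilities) - 1.0) > 1e-9:
            raise ValidationError(
                f"cluster probabilities must sum to 1, got {sum(self.probabilities)}"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Numerical controls for the hybrid loop and readouts."""

    dt_sync_min: float = 0.1
    record_grid_min: float = 1.0
    t_max_min: float = 1440.0
    rk_substep_min: float = 0.02
    death_threshold_rate_nm_min: float = 0.0394
    ligand_mass_kda: float = 19.6
    cv_on: str = "rate"  # "rate" | "increments"

    def __post_init__(self):
        for name in ("dt_sync_min", "record_grid_min", "t_max_min", "rk_substep_min",
                     "death_threshold_rate_nm_min", "ligand_mass_kda"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"'{name}' must be > 0")
        if self.cv_on not in ("rate", "increments"):
            raise ValidationError(f"cv_on must be 'rate' or 'increments', got {self.cv_on!r}")


@dataclass(frozen=True)
class ModelConfig:
    """Complete model parameterisation."""

    geometry: CellGeometry = field(default_factory=CellGeometry)
    initial_nm: InitialConcentrations = field(default_factory=InitialConcentrations)
    rates: KineticParameters = field(default_factory=KineticParameters)
    masses_kda: SubunitMasses = field(default_factory=SubunitMasses)
    receptors: Mapping[str, ReceptorSpec] = field(
        default_factory=lambda: {
            "tnfr1": ReceptorSpec(905, 1.0),
            "dr4": ReceptorSpec(769, 1.0),
            "dr5": ReceptorSpec(926, 1.0),
        }
    )
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    metadata: Mapping[str, Any] = field(default_factory=dict)

    @property
    def copies_per_nm(self) -> float:
        return self.geometry.copies_per_nm

    def to_dict(self) -> dict:
        d = {
            "geometry": asdict(self.geometry),
            "initial_nm": asdict(self.initial_nm),
            "rates": asdict(self.rates),
            "masses_kda": asdict(self.masses_kda),
            "receptors": {k: asdict(v) for k, v in self.receptors.items()},
            "clustering": {
                "sizes": list(self.clustering.sizes),
                "probabilities": list(self.clustering.probabilities),
            },
            "simulation": asdict(self.simulation),
            "metadata": copy.deepcopy(dict(self.metadata)),
        }
        return d

    def replace(self, **section_updates) -> "ModelConfig":
        """Return a copy with whole sections or nested keys replaced.

        ``cfg.replace(rates={"kcat_ub": 2.0})`` updates a single rate;
        passing a dataclass instance replaces the whole section.
        """
        kwargs = {}
        for name, value in section_updates.items():
            current = getattr(self, name)
            if isinstance(value, dict) and not isinstance(current, dict):
                kwargs[name] = type(current)(**{**asdict(current), **value})
            else:
                kwargs[name] = value
        merged = {
            "geometry": self.geometry,
            "initial_nm": self.initial_nm,
            "rates": self.rates,
            "masses_kda": self.masses_kda,
            "receptors": self.receptors,
            "clustering": self.clustering,
            "simulation": self.simulation,
            "metadata": self.metadata,
        }
        merged.update(kwargs)
        return ModelConfig(**merged)


_SECTION_TYPES = {
    "geometry": CellGeometry,
    "initial_nm": InitialConcentrations,
    "rates": KineticParameters,
    "masses_kda": SubunitMasses,
    "simulation": SimulationConfig,
}

_REQUIRED_SECTIONS = (
    "geometry", "initial_nm", "rates", "masses_kda",
    "receptors", "clustering", "simulation",
)


def _build_section(name: str, cls, data: Mapping[str, Any]):
    valid = {f.name for f in dc_fields(cls)}
    for key in data:
        if key not in valid:
            raise UnknownKeyError(name, key)
    for key in valid:
        if key not in data:
            # geometry.avogadro is a fixed constant, never required in files
            if name == "geometry" and key == "avogadro":
                continue
            raise MissingKeyError(name, key)
    return cls(**data)


def _parse_config_dict(doc: Mapping[str, Any], base_dir: Path | None = None) -> ModelConfig:
    if not isinstance(doc, Mapping):
        raise ValidationError("config document must be a mapping")
    known = set(_REQUIRED_SECTIONS) | {"metadata"}
    for key in doc:
        if key not in known:
            raise UnknownKeyError("<root>", key)
    for sec in _REQUIRED_SECTIONS:
        if sec not in doc:
            raise MissingKeyError("<root>", sec)

    sections = {}
    for name, cls in _SECTION_TYPES.items():
        sections[name] = _build_section(name, cls, doc[name])

    rec_doc = doc["receptors"]
    receptors = {}
    for rname in ("tnfr1", "dr4", "dr5"):
        if rname not in rec_doc:
            raise MissingKeyError("receptors", rname)
        entry = rec_doc[rname]
        for key in entry:
            if key not in ("count", "kd_nm"):
                raise UnknownKeyError(f"receptors.{rname}", key)
        for key in ("count", "kd_nm"):
            if key not in entry:
                raise MissingKeyError(f"receptors.{rname}", key)
        receptors[rname] = ReceptorSpec(**entry)
    for key in rec_doc:
        if key not in ("tnfr1", "dr4", "dr5"):
            raise UnknownKeyError("receptors", key)

    cl_doc = dict(doc["clustering"])
    for key in cl_doc:
        if key not in ("sizes", "probabilities", "table_csv"):
            raise UnknownKeyError("clustering", key)
    if "table_csv" in cl_doc:
        csv_path = Path(cl_doc.pop("table_csv"))
        if base_dir is not None and not csv_path.is_absolute():
            csv_path = base_dir / csv_path
        sizes, probs = _read_cluster_csv(csv_path)
        clustering = ClusteringConfig(sizes=sizes, probabilities=probs)
    else:
        for key in ("sizes", "probabilities"):
            if key not in cl_doc:
                raise MissingKeyError("clustering", key)
        clustering = ClusteringConfig(
            sizes=tuple(cl_doc["sizes"]), probabilities=tuple(cl_doc["probabilities"])
        )

    return ModelConfig(
        geometry=sections["geometry"],
        initial_nm=sections["initial_nm"],
        rates=sections["rates"],
        masses_kda=sections["masses_kda"],
        receptors=receptors,
        clustering=clustering,
        simulation=sections["simulation"],
        metadata=dict(doc.get("metadata", {})),
    )


def _read_cluster_csv(path: Path):
    """Two-column CSV (size_trimers, probability)."""
    sizes, probs = [], []
    try:
        lines = Path(path).read_text().strip().splitlines()
    except OSError as exc:
        raise ValidationError(f"cannot read cluster table '{path}': {exc}") from exc
    for i, line in enumerate(lines):
        line = line.strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if i == 0 and not parts[0].lstrip("-").replace(".", "").isdigit():
            continue  # header
        if len(parts) != 2:
            raise ValidationError(f"malformed cluster table row: {line!r}")
        sizes.append(int(float(parts[0])))
        probs.append(float(parts[1]))
    return tuple(sizes), tuple(probs)


def load_model_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML/JSON model configuration file.

    Raises :class:`MissingKeyError`, :class:`UnknownKeyError` or
    :class:`ValidationError` (all subclasses of :class:`ConfigError`, each with
    a distinct ``code``) on schema violations.  Loading is side-effect-free and
    idempotent.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValidationError(f"malformed config file {path}: {exc}") from exc
    return _parse_config_dict(doc, base_dir=path.parent)


def default_config() -> ModelConfig:
    """The shipped default configuration (see ``data/default_config.yaml``)."""
    with resources.as_file(
        resources.files("ripoptosim").joinpath("data/default_config.yaml")
    ) as p:
        return load_model_config(p)
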