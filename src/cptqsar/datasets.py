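"""Packaged study data and synthetic-data generators.

Fixtures
--------
The package ships the study's printed data as text fixtures, checksummed so
silent transcription drift fails loudly:

* ``table1.csv`` — LC50 (mmol/L) of the 28 derivatives plus the parent
  compound (id ``"1"``) against the three test species;
* ``table3.csv`` — experimental and model-predicted pLC50 for the 28
  derivatives, with the 23/5 train/test split and the printed residuals
  (one printed row is internally inconsistent and is flagged, not repaired);
* ``compounds.smi`` — SMILES for all 29 compounds, reconstructed from the
  compound names and verified against the printed molecular formulas;
* ``scaffold.smarts`` — the 28-atom common-substructure query used for the
  template alignment.

Generators
----------
Synthetic inputs with the statistical structure the analysis assumes, for
parameter-recovery validation: a QSAR generator planting a known linear
activity signal in a smooth random field matrix, and a bioassay generator
drawing binomial dead counts from a probit dose-mortality curve with
natural control mortality.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import FixtureIntegrityError, SchemaError
from .fields import FieldMatrix, GridSpec, ProbeAtom
from .bioassay import DoseResponseSeries

__all__ = [
    "PaperFixture",
    "load_paper_fixture",
    "SyntheticQSARSpec",
    "generate_qsar_data",
    "SyntheticBioassaySpec",
    "generate_bioassay_data",
    "TEST_COMPOUNDS",
    "TEMPLATE_ID",
    "QSAR_SPECIES",
]

#: Compounds held out of the model fit as the external test set.
TEST_COMPOUNDS = frozenset({"4a", "4i", "4l", "5b", "5g"})

#: Alignment template: the most active derivative.
TEMPLATE_ID = "4d"

#: Species whose activities the QSAR models.
QSAR_SPECIES = "T_cinnabarinus"

_CHECKSUMS = {
    "compounds.smi": "d5c92cad61fff28e54c079e2ace54fcae8cd4267615af3404d01c048bdc2033e",
    "scaffold.smarts": "6c74358ff19929ce173b6c0c8d9ddfa5ded722e9e3d08f7cfe860c81b68bf724",
    "table1.csv": "0274e1a0c467f8c49f079cbee1ee61c0db0154173359d773387090ea17a6b121",
    "table3.csv": "065948958d91f4f06a828f5452f38d16471d23cf8cde49783d1ed067d6af5f70",
}


@dataclass
class PaperFixture:
    """The packaged study tables plus structures and scaffold query."""

    activity_table: pd.DataFrame  # compound, species, lc50_mM (29 x 3 rows)
    qsar_table: pd.DataFrame  # compound, plc50_exp, plc50_pred, residual, role
    compounds: dict[str, str]  # id -> SMILES (29 entries)
    scaffold_smarts: str
    template_id: str = TEMPLATE_ID

    @property
    def train_ids(self) -> list[str]:
        return list(self.qsar_table.loc[self.qsar_table.role == "train", "compound"])

    @property
    def test_ids(self) -> list[str]:
        return list(self.qsar_table.loc[self.qsar_table.role == "test", "compound"])


def _read_bytes(name: str) -> bytes:
    data = resources.files("cptqsar.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureIntegrityError(
            f"packaged file {name} has checksum {digest}, expected "
            f"{_CHECKSUMS[name]}; the fixture has been altered"
        )
    return data


def load_paper_fixture() -> PaperFixture:
    """Load and checksum-verify the packaged study data."""
    import io

    activity = pd.read_csv(io.BytesIO(_read_bytes("table1.csv")))
    qsar = pd.read_csv(io.BytesIO(_read_bytes("table3.csv")))
    compounds: dict[str, str] = {}
    for line in _read_bytes("compounds.smi").decode().splitlines():
        if not line.strip():
            continue
        smi, cid = line.split()
        compounds[cid] = smi
    scaffold = _read_bytes("scaffold.smarts").decode().strip()
    if len(compounds) != 29 or len(qsar) != 28:
        raise FixtureIntegrityError("unexpected fixture sizes")
    return PaperFixture(
        activity_table=activity,
        qsar_table=qsar,
        compounds=compounds,
        scaffold_smarts=scaffold,
    )


# ---------------------------------------------------------------------------
# synthetic QSAR data


@dataclass(frozen=True)
class SyntheticQSARSpec:
    """Planted-signal field-matrix generator settings.

    ``planted_columns`` index into the full column set (steric block first);
    activity is their linear combination with ``planted_coefficients`` plus
    Gaussian noise of sd ``noise_sd`` (pLC50 units).

    Generated matrices copy the structure of real probe-field matrices over
    an aligned congeneric series: the molecules differ in a small number of
    substituent features, so the field is approximately low-rank —
    ``n_factors`` smooth spatial patterns (random atom-like deposits under
    an isotropic Gaussian blur, sd one grid step) weighted by per-molecule
    standard-normal loadings — plus a sharp short-range component
    (``roughness_sd``) of the kind steric potentials show at molecular
    surfaces.  The smooth low-rank part gives realistic collinearity and
    minimum-sigma behavior and makes ``n_factors`` the model's true latent
    dimensionality; the sharp part keeps the design full-rank, so the
    planted coefficients stay statistically identifiable.
    """

    n_molecules: int = 28
    planted_columns: tuple[int, ...] | None = None  # None: strongest column per factor
    planted_coefficients: tuple[float, ...] = (0.08, -0.05, 0.06)
    noise_sd: float = 0.05
    seed: int = 0
    n_factors: int = 3
    field_scale: float = 20.0  # kcal/mol spread of the atom-like deposits
    roughness_sd: float = 1.0  # kcal/mol sharp component per column
    n_deposits: int = 30

    def __post_init__(self) -> None:
        if (
            self.planted_columns is not None
            and len(self.planted_columns) != len(self.planted_coefficients)
        ):
            raise SchemaError("planted columns and coefficients must pair up")
        if self.planted_columns is None and len(self.planted_coefficients) > self.n_factors:
            raise SchemaError("auto-placement needs one factor per planted coefficient")
        if self.noise_sd < 0:
            raise SchemaError("noise_sd must be >= 0")


def generate_qsar_data(
    spec: SyntheticQSARSpec, grid: GridSpec
) -> tuple[FieldMatrix, np.ndarray, dict]:
    """Generate a structured random field matrix and planted linear activities.

    Returns a :class:`FieldMatrix` (two blocks over ``grid``), the activity
    vector, and a truth dict (``planted_columns``, ``coefficients``) — with
    auto-placement the signal sits at each factor's strongest column, i.e.
    where that substituent feature actually moves the field.  Deterministic
    for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = grid.shape
    n_pts = int(np.prod(shape))
    n_cols = 2 * n_pts
    if spec.planted_columns is not None:
        for c in spec.planted_columns:
            if not 0 <= c < n_cols:
                raise SchemaError(
                    f"planted column {c} outside the {n_cols}-column grid"
                )
    # per-molecule loadings on the latent substituent features, shared by
    # both blocks (a substituent shapes steric and electrostatic fields alike)
    loadings = rng.normal(0.0, 1.0, size=(spec.n_molecules, spec.n_factors))
    blocks = []
    all_patterns = []
    for _ in range(2):  # steric-like and electrostatic-like block
        patterns = np.empty((spec.n_factors, n_pts))
        for f in range(spec.n_factors):
            vol = np.zeros(shape)
            ijk = rng.integers(0, shape, size=(spec.n_deposits, 3))
            amp = rng.normal(0.0, spec.field_scale, size=spec.n_deposits)
            np.add.at(vol, (ijk[:, 0], ijk[:, 1], ijk[:, 2]), amp)
            patterns[f] = ndimage.gaussian_filter(vol, sigma=1.0).ravel()
        rows = loadings @ patterns + rng.normal(
            0.0, spec.roughness_sd, size=(spec.n_molecules, n_pts)
        )
        blocks.append(rows)
        all_patterns.append(patterns)
    values = np.hstack(blocks)
    planted = spec.planted_columns
    if planted is None:
        # strongest column of each factor across both blocks, deduplicated
        pattern_cols = np.hstack(all_patterns)  # (n_factors, 2*n_pts)
        chosen: list[int] = []
        for f in range(len(spec.planted_coefficients)):
            order = np.argsort(-np.abs(pattern_cols[f]))
            chosen.append(int(next(c for c in order if c not in chosen)))
        planted = tuple(chosen)
    beta = np.zeros(n_cols)
    beta[list(planted)] = spec.planted_coefficients
    y = values @ beta + rng.normal(0.0, spec.noise_sd, size=spec.n_molecules)
    fm = FieldMatrix(
        compound_ids=[f"syn{i:03d}" for i in range(spec.n_molecules)],
        values=values,
        grid=grid,
        cutoff=np.inf,
        excluded_mask=np.zeros((spec.n_molecules, n_pts), dtype=bool),
        es_mode="clamp",
        probe=ProbeAtom(),
    )
    truth = {
        "planted_columns": planted,
        "coefficients": tuple(spec.planted_coefficients),
    }
    return fm, y, truth


# ---------------------------------------------------------------------------
# synthetic bioassay data


@dataclass(frozen=True)
class SyntheticBioassaySpec:
    """Probit dose-mortality generator settings (study design defaults).

    The defaults mirror the bioassay design: five serial concentrations
    bracketing the true LC50, 30 organisms per dose, a triplicate control
    group (3 x 30 organisms), and a small natural control mortality.
    """

    true_lc50: float = 0.05  # mmol/L
    slope: float = 2.5  # probits per log10 dose
    doses: tuple[float, ...] = (0.0125, 0.025, 0.05, 0.1, 0.2)
    n_per_dose: int = 30
    control_mortality: float = 0.05
    n_control: int = 90
    seed: int = 0
    compound: str = "synthetic"
    species: str = "synthetic"

    def __post_init__(self) -> None:
        if not 0 <= self.control_mortality < 1:
            raise SchemaError("control mortality must be in [0, 1)")
        if not (min(self.doses) <= self.true_lc50 <= max(self.doses)):
            raise SchemaError("doses must bracket the true LC50")


def true_mortality(spec: SyntheticBioassaySpec, dose: np.ndarray) -> np.ndarray:
    """Expected observed mortality p = c + (1-c) * Phi(beta*(log d - log LC50))."""
    z = spec.slope * (np.log10(np.asarray(dose)) - np.log10(spec.true_lc50))
    c = spec.control_mortality
    return c + (1.0 - c) * stats.norm.cdf(z)


def generate_bioassay_data(spec: SyntheticBioassaySpec) -> DoseResponseSeries:
    """Draw binomial dead counts from the probit curve; includes a control."""
    rng = np.random.default_rng(spec.seed)
    doses = np.asarray(sorted(spec.doses), dtype=float)
    p = true_mortality(spec, doses)
    dead = rng.binomial(spec.n_per_dose, p)
    control_dead = rng.binomial(spec.n_control, spec.control_mortality)
    return DoseResponseSeries(
        compound=spec.compound,
        species=spec.species,
        doses=doses,
        n_exposed=np.full(doses.size, spec.n_per_dose),
        n_dead=dead,
        control_exposed=spec.n_control,
        control_dead=int(control_dead),
    )
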