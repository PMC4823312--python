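"""Orchestration of the skull-defect simulation study.

Builds the synthetic phantom with two cylindrical skull defects, forward
models with intact skull (``I``) and with the defects incorporated (``D``),
synthesizes "measurement" field maps from the ground-truth defect model
(agar conductivity 1.0 S/m, source strength 130 uAmm), and runs:

* forward concordance: intact vs defect maps across shift positions and a
  defect-conductivity sweep, with RDM*/MAG_rel tables and difference maps;
* the three reconstruction configurations i-I, d-I and d-D (intact data /
  intact model, defect data / intact model, defect data / defect model);
* the defect-conductivity variation of the reconstruction model;
* the single-tissue conductivity sensitivity analysis;
* the gradiometer base-length uniformization check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .dipolefit import FitConfig, ReconResult, fit_moving_dipole, \
    project_moment_inplane
from .fem import Dipole, FieldMap, ForwardModel
from .hexmesh import HexMesh, apply_node_shift, voxels_to_hexmesh
from .metrics import SourceCharacterization, characterize_sources, \
    compare_maps, mag_rel, rdm_star, summarize_characterizations
from .phantom import DefectSpec, LabeledVoxelGrid, LayerRadii, PhantomConfig, \
    SensorArray, SensorArrayConfig, ShiftLine, Tissue, TissueTable, \
    build_phantom, carve_defects, draw_base_lengths, make_sensor_array

#: defect conductivity sweep of the forward study, S/m
DEFAULT_DEFECT_CONDUCTIVITIES = (1e-6, 0.004, 0.046, 0.1, 0.2, 0.4, 0.6,
                                 0.8, 1.0)

#: tissues and fractional changes of the sensitivity analysis
SENSITIVITY_TISSUES = (Tissue.COMPACT_BONE, Tissue.CANCELLOUS_BONE,
                       Tissue.GRAY_MATTER, Tissue.WHITE_MATTER)
SENSITIVITY_FRACTIONS = (-0.5, -0.2, -0.1, 0.1, 0.2, 0.5)

RECONSTRUCTION_CONFIGURATIONS = ("i-I", "d-I", "d-D")


@dataclass(frozen=True)
class StudyConfig:
    """Full parameterization of one study run."""

    phantom: PhantomConfig
    defects: tuple[DefectSpec, ...]
    sensors: SensorArrayConfig
    line: ShiftLine
    tissue_table: TissueTable = field(default_factory=TissueTable)
    node_shift: float = 0.49
    defect_conductivities: tuple[float, ...] = DEFAULT_DEFECT_CONDUCTIVITIES
    truth_defect_conductivity: float = 1.0
    source_strength: float = 130.0          # uAmm
    snr_db: float | None = None             # None -> noiseless
    seed: int = 0
    under_window: float = 0.5               # |eccentricity| <= w
    next_window: float = 1.3                # |eccentricity| >= w
    solver_method: str = "pcg"
    solver_tol: float = 1e-8
    fit: FitConfig = field(default_factory=FitConfig)

    @property
    def primary_defect(self) -> DefectSpec:
        return self.defects[0]

    def source_moment(self) -> np.ndarray:
        return self.source_strength * self.line.unit_direction

    def truth_dipoles(self, indices: Sequence[int] | None = None
                      ) -> list[Dipole]:
        if indices is None:
            indices = self.line.full_step_indices()
        mom = tuple(self.source_moment())
        return [Dipole(tuple(self.line.position(i)), mom) for i in indices]


def default_study_config(voxel_size: float = 0.8,
                         shape: str = "ellipsoid",
                         snr_db: float | None = None,
                         seed: int = 0,
                         n_positions: int = 23,
                         line_center_offset: float = -1.1,
                         ) -> StudyConfig:
    """The bundled desk-scale study setup.

    A ~3 cm layered head meshed at ``voxel_size`` resolution, two
    5 mm-diameter skull defects on top of the head 7 mm apart, a tangential
    source line 1.5 mm below the inner skull surface shifted in 0.3455 mm
    half-steps under defect 1, and the 16-channel planar axial gradiometer
    array with 30 mm base length.  The skull layers of the desk-scale study
    are 0.8 mm each (compact--cancellous--compact) so that all three are
    resolved at the default 0.8 mm mesh.
    """
    radii = LayerRadii(scalp=15.0, skull_outer=14.0, cancellous_outer=13.2,
                       cancellous_inner=12.4, skull_inner=11.6, white=9.6)
    phantom = PhantomConfig(shape=shape, radii=radii, voxel_size=voxel_size)
    sz = phantom.scales[2]
    skull_surface_z = radii.skull_outer * sz
    # defect 2 sits laterally offset from the shift line: a fully
    # mirror-symmetric arrangement would structurally suppress the
    # source-reorientation effect next to the defects (perfectly symmetric
    # spherical models show no orientation errors), so the phantom keeps
    # the asymmetry of the physical experiment
    defects = (
        DefectSpec(center=(0.0, 0.0, skull_surface_z), radius=2.5,
                   axis=(0.0, 0.0, 1.0)),
        DefectSpec(center=(-7.0, 2.0, skull_surface_z), radius=2.5,
                   axis=(0.0, 0.0, 1.0)),
    )
    source_z = radii.skull_inner * sz - 1.5
    half_step = 0.3455
    origin_x = line_center_offset - (n_positions - 1) / 2.0 * half_step
    line = ShiftLine(origin=(origin_x, 0.0, source_z),
                     direction=(1.0, 0.0, 0.0),
                     n_positions=n_positions, half_step=half_step)
    sensors = SensorArrayConfig(plane_z=radii.scalp * sz + voxel_size + 3.0)
    return StudyConfig(phantom=phantom, defects=defects, sensors=sensors,
                       line=line, snr_db=snr_db, seed=seed)


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def _mesh_from_grid(grid: LabeledVoxelGrid, table: TissueTable,
                    node_shift: float) -> HexMesh:
    mesh = voxels_to_hexmesh(grid, table)
    if node_shift > 0:
        mesh = apply_node_shift(mesh, node_shift, grid)
    return mesh


@dataclass
class StudyModels:
    """Phantom grids, meshes and forward models of one study setup.

    The intact and defect meshes share node numbering (the defects only
    relabel voxels), so fitted positions are directly comparable.
    """

    config: StudyConfig
    grid_intact: LabeledVoxelGrid
    grid_defect: LabeledVoxelGrid
    mesh_intact: HexMesh
    mesh_defect: HexMesh
    array: SensorArray
    intact: ForwardModel
    _defect_models: dict = field(default_factory=dict)

    @property
    def truth(self) -> ForwardModel:
        """Ground-truth model: defects at the physical agar conductivity."""
        return self.defect_model(self.config.truth_defect_conductivity)

    def defect_model(self, defect_sigma: float) -> ForwardModel:
        """Defect-skull forward model with the given defect conductivity."""
        key = float(defect_sigma)
        if key not in self._defect_models:
            table = self.config.tissue_table.with_overrides(
                agar_defect=defect_sigma)
            mesh = self.mesh_defect.set_conductivities(table)
            self._defect_models[key] = ForwardModel(
                mesh, self.array, grid=self.grid_defect,
                tol=self.config.solver_tol, method=self.config.solver_method,
                model_id=f"D[{defect_sigma:g} S/m]")
        return self._defect_models[key]

    def intact_model_with_table(self, table: TissueTable) -> ForwardModel:
        mesh = self.mesh_intact.set_conductivities(table)
        return ForwardModel(mesh, self.array, grid=self.grid_intact,
                            tol=self.config.solver_tol,
                            method=self.config.solver_method, model_id="I*")

    def defect_model_with_table(self, table: TissueTable) -> ForwardModel:
        mesh = self.mesh_defect.set_conductivities(table)
        return ForwardModel(mesh, self.array, grid=self.grid_defect,
                            tol=self.config.solver_tol,
                            method=self.config.solver_method, model_id="D*")


def build_models(cfg: StudyConfig) -> StudyModels:
    """Build phantom grids, meshes, the sensor array and the intact model."""
    grid_intact = build_phantom(cfg.phantom)
    grid_defect = carve_defects(grid_intact, cfg.defects)
    mesh_intact = _mesh_from_grid(grid_intact, cfg.tissue_table,
                                  cfg.node_shift)
    mesh_defect = _mesh_from_grid(grid_defect, cfg.tissue_table,
                                  cfg.node_shift)
    array = make_sensor_array(cfg.sensors)
    intact = ForwardModel(mesh_intact, array, grid=grid_intact,
                          tol=cfg.solver_tol, method=cfg.solver_method,
                          model_id="I")
    return StudyModels(cfg, grid_intact, grid_defect, mesh_intact,
                       mesh_defect, array, intact)


# ---------------------------------------------------------------------------
# measurement synthesis
# ---------------------------------------------------------------------------

def add_noise(fmap: FieldMap, snr_db: float,
              rng: np.random.Generator) -> FieldMap:
    """Add white Gaussian noise at the given SNR (dB, rms signal/noise)."""
    rms = np.sqrt(np.mean(fmap.values ** 2))
    noise_std = rms * 10.0 ** (-snr_db / 20.0)
    noisy = fmap.values + rng.normal(0.0, noise_std, size=fmap.values.shape)
    out = FieldMap(noisy, meta=dict(fmap.meta))
    out.meta["snr_db"] = snr_db
    return out


def synthesize_measurements(cfg: StudyConfig, models: StudyModels,
                            indices: Sequence[int] | None = None,
                            model: ForwardModel | None = None,
                            ) -> list[FieldMap]:
    """Stand-in measurement maps from the ground-truth model.

    Forward maps of the 130 uAmm truth dipoles computed in the defect model
    at the physical agar conductivity (or a caller-supplied model, e.g. the
    intact model for the i-I configuration), with optional additive white
    noise at ``cfg.snr_db``.  Deterministic for a given seed.
    """
    if indices is None:
        indices = cfg.line.full_step_indices()
    if model is None:
        model = models.truth
    rng = np.random.default_rng(cfg.seed)
    maps = []
    for dip in cfg.truth_dipoles(indices):
        fmap = model.field_map(dip)
        fmap.meta["truth_dipole"] = dip
        if cfg.snr_db is not None:
            fmap = add_noise(fmap, cfg.snr_db, rng)
        maps.append(fmap)
    return maps


# ---------------------------------------------------------------------------
# forward concordance and defect-conductivity sweep
# ---------------------------------------------------------------------------

@dataclass
class ForwardConcordance:
    """Intact/defect map pairs and their comparison metrics."""

    table: pd.DataFrame                     # one row per (index, sigma)
    intact_maps: dict                       # index -> FieldMap
    defect_maps: dict                       # (index, sigma) -> FieldMap
    difference_maps: dict                   # (index, sigma) -> np.ndarray


def run_forward_concordance(cfg: StudyConfig, models: StudyModels,
                            conductivities: Sequence[float] | None = None,
                            indices: Sequence[int] | None = None,
                            ) -> ForwardConcordance:
    """Forward maps and RDM*/MAG_rel across positions and defect sigmas.

    The reference of each comparison is the same-position intact-skull map;
    difference maps (defect minus intact) support the rotation analysis of
    the defect-induced signal component.
    """
    if conductivities is None:
        conductivities = cfg.defect_conductivities
    if indices is None:
        indices = cfg.line.full_step_indices()
    dipoles = cfg.truth_dipoles(indices)
    intact_maps = {i: models.intact.field_map(d)
                   for i, d in zip(indices, dipoles)}
    rows, defect_maps, diff_maps = [], {}, {}
    from .phantom import compute_shift_eccentricity
    for sigma in conductivities:
        dm = models.defect_model(sigma)
        for i, dip in zip(indices, dipoles):
            fmap = dm.field_map(dip)
            defect_maps[(i, sigma)] = fmap
            diff_maps[(i, sigma)] = fmap.values - intact_maps[i].values
            ecc = compute_shift_eccentricity(dip.pos, cfg.primary_defect,
                                             cfg.line)
            rows.append({
                "position_index": i,
                "eccentricity": ecc,
                "defect_sigma": sigma,
                "mag_rel": mag_rel(intact_maps[i], fmap),
                "rdm_star": rdm_star(intact_maps[i], fmap),
            })
    return ForwardConcordance(pd.DataFrame(rows), intact_maps, defect_maps,
                              diff_maps)


# ---------------------------------------------------------------------------
# reconstruction configurations
# ---------------------------------------------------------------------------

@dataclass
class ReconstructionRun:
    """Fits and characterizations of one reconstruction configuration."""

    configuration: str
    results: list[ReconResult]
    fitted: list[Dipole]                    # in-plane projected moments
    characterizations: list[SourceCharacterization]
    summary: pd.DataFrame
    measurements: list[FieldMap]


def run_reconstruction(cfg: StudyConfig, models: StudyModels,
                       configuration: str = "d-D",
                       indices: Sequence[int] | None = None,
                       measurements: list[FieldMap] | None = None,
                       fit_model: ForwardModel | None = None,
                       ) -> ReconstructionRun:
    """Fit every shift-position map in one configuration.

    ``i-I``: intact-skull data, intact model; ``d-I``: defect data, intact
    model (defects ignored); ``d-D``: defect data, defect model.  The moment
    component normal to the coil plane is zeroed after each fit; fits are
    characterized against the physical sources.
    """
    if configuration not in RECONSTRUCTION_CONFIGURATIONS:
        raise ValueError(
            f"configuration must be one of {RECONSTRUCTION_CONFIGURATIONS}, "
            f"got {configuration!r}"
        )
    if indices is None:
        indices = cfg.line.full_step_indices()
    if measurements is None:
        data_model = models.intact if configuration == "i-I" else models.truth
        measurements = synthesize_measurements(cfg, models, indices,
                                               model=data_model)
    if fit_model is None:
        fit_model = models.truth if configuration == "d-D" else models.intact

    truths = cfg.truth_dipoles(indices)
    results, fitted = [], []
    for fmap, truth in zip(measurements, truths):
        res = fit_moving_dipole(fmap, fit_model, truth.pos, cfg.fit)
        results.append(res)
        mom = project_moment_inplane(res.dipole.mom,
                                     models.array.plane_normal)
        fitted.append(Dipole(res.dipole.position, tuple(mom)))
    chars = characterize_sources(fitted, truths, cfg.line,
                                 cfg.primary_defect,
                                 under_window=cfg.under_window,
                                 next_window=cfg.next_window)
    return ReconstructionRun(configuration, results, fitted, chars,
                             summarize_characterizations(chars),
                             measurements)


def run_defect_conductivity_variation(cfg: StudyConfig, models: StudyModels,
                                      model_conductivities:
                                      Sequence[float] | None = None,
                                      indices: Sequence[int] | None = None,
                                      ) -> pd.DataFrame:
    """d-D fits with the model's defect conductivity swept.

    Measurements always come from the physical 1.0 S/m truth model; the fit
    model's defect conductivity takes each value of the sweep.  Returns one
    row per (model sigma, position) with position error and strength.
    """
    if model_conductivities is None:
        model_conductivities = cfg.defect_conductivities
    if indices is None:
        indices = cfg.line.full_step_indices()
    measurements = synthesize_measurements(cfg, models, indices)
    truths = cfg.truth_dipoles(indices)
    rows = []
    for sigma in model_conductivities:
        fit_model = models.defect_model(sigma)
        run = run_reconstruction(cfg, models, "d-D", indices,
                                 measurements=measurements,
                                 fit_model=fit_model)
        for i, char, res in zip(indices, run.characterizations, run.results):
            rows.append({
                "model_sigma": sigma,
                "position_index": i,
                "eccentricity": char.eccentricity,
                "group": char.group,
                "position_error": char.position_error,
                "angle_to_shift": char.angle_to_shift,
                "strength": char.strength,
                "explained_variance": res.explained_variance,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

def sensitivity_grid(table: TissueTable | None = None,
                     tissues: Sequence[Tissue] = SENSITIVITY_TISSUES,
                     fractions: Sequence[float] = SENSITIVITY_FRACTIONS,
                     ) -> pd.DataFrame:
    """Perturbed single-tissue conductivities (S/m) of the sensitivity grid."""
    table = table or TissueTable()
    rows = []
    for tissue in tissues:
        row = {"tissue": tissue.name.lower()}
        for frac in fractions:
            row[f"{frac:+.0%}"] = table[tissue] * (1.0 + frac)
        rows.append(row)
    return pd.DataFrame(rows)


def run_sensitivity(cfg: StudyConfig, models: StudyModels,
                    configuration: str = "d-D",
                    tissues: Sequence[Tissue] = SENSITIVITY_TISSUES,
                    fractions: Sequence[float] = SENSITIVITY_FRACTIONS,
                    indices: Sequence[int] | None = None) -> pd.DataFrame:
    """Refit with single-tissue conductivity perturbations.

    Measurements are fixed (truth model, unperturbed conductivities); the
    reconstruction model's tissue table is perturbed one tissue at a time.
    Reports the median displacement of fitted positions relative to the
    unperturbed baseline fit.
    """
    if indices is None:
        indices = cfg.line.full_step_indices()
    measurements = synthesize_measurements(
        cfg, models, indices,
        model=models.intact if configuration == "i-I" else models.truth)
    baseline = run_reconstruction(cfg, models, configuration, indices,
                                  measurements=measurements)
    base_pos = np.array([d.pos for d in baseline.fitted])
    rows = []
    for tissue in tissues:
        for frac in fractions:
            table = cfg.tissue_table.perturbed(int(tissue), frac)
            if configuration == "d-D":
                table = table.with_overrides(
                    agar_defect=cfg.truth_defect_conductivity)
                fit_model = models.defect_model_with_table(table)
            else:
                fit_model = models.intact_model_with_table(table)
            run = run_reconstruction(cfg, models, configuration, indices,
                                     measurements=measurements,
                                     fit_model=fit_model)
            disp = np.linalg.norm(
                np.array([d.pos for d in run.fitted]) - base_pos, axis=1)
            rows.append({
                "tissue": tissue.name.lower(),
                "fraction": frac,
                "sigma": table[int(tissue)],
                "median_displacement": float(np.median(disp)),
                "max_displacement": float(np.max(disp)),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# base-length uniformization
# ---------------------------------------------------------------------------

def run_baselength_check(cfg: StudyConfig, models: StudyModels,
                         seed: int | None = None,
                         low: float = 28.5, high: float = 31.5):
    """Forward-map deviation of non-uniform vs uniform 30 mm base lengths.

    One tangential source centered under defect 1 is simulated with the
    uniform array and with per-channel base lengths drawn reproducibly from
    [low, high] mm; returns the MapComparison (RDM*, MAG_rel) with the
    uniform-array map as reference.
    """
    seed = cfg.seed if seed is None else seed
    base = draw_base_lengths(cfg.sensors, seed, low, high)
    array_var = models.array.with_base_lengths(base)
    model_var = ForwardModel(models.intact.mesh, array_var,
                             grid=models.grid_intact,
                             tol=cfg.solver_tol, method=cfg.solver_method,
                             model_id="I[base-length draw]")
    center = _centered_dipole(cfg)
    map_uniform = models.intact.field_map(center)
    map_var = model_var.field_map(center)
    return compare_maps(map_uniform, map_var,
                        reference_id="uniform 30 mm",
                        test_id=f"drawn [{low}, {high}] mm, seed {seed}")


def _centered_dipole(cfg: StudyConfig) -> Dipole:
    """The truth dipole closest to the center of defect 1."""
    from .phantom import compute_shift_eccentricity
    best = min(
        cfg.line.full_step_indices(),
        key=lambda i: abs(compute_shift_eccentricity(
            cfg.line.position(i), cfg.primary_defect, cfg.line)),
    )
    return cfg.truth_dipoles([best])[0]
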