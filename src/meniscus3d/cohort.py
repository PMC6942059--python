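"""Simulated CT-vs-MRI agreement study on a phantom cohort.

Runs the full validation workflow end to end on ``n`` synthetic subjects:
phantom generation, CT-like and MRI-like acquisition of the tibia (the
meniscus is segmented from MRI only, as in practice), frame fitting on the
CT model, ICP transfer to the MRI model, extrusion measurement against both
tibial references, single-slice 2D width, and the agreement statistics —
per-subject surface differences, modality comparisons with effect sizes and
power, and consistency regressions.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import pandas as pd

from . import validity_stats as vs
from .extrusion_core import (
    MeasurementParams,
    compute_2d_width,
    coronal_contours,
    measure_extrusion,
    select_coronal_slice,
)
from .phantom import (
    MeniscusSpec,
    OsteophyteSpec,
    PhantomSpec,
    emulate_acquisition,
    make_phantom,
)
from .surface_compare import (
    cohort_summary,
    plateau_metrics,
    signed_surface_difference,
)
from .tibial_frame import fit_tibial_frame, icp_register, transfer_frame


@dataclasses.dataclass
class CohortReport:
    """Per-subject measurements and the three study-style tables."""

    subjects: pd.DataFrame
    comparison_table: pd.DataFrame  # modality comparison (per variable)
    surface_table: pd.DataFrame  # per-subject surface differences
    regression_table: pd.DataFrame  # consistency regressions
    surface_min_mean: float
    surface_max_mean: float

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.subjects.to_csv(os.path.join(out_dir, "subjects.csv"), index=False)
        self.comparison_table.to_csv(
            os.path.join(out_dir, "modality_comparison.csv"), index=False
        )
        self.surface_table.to_csv(
            os.path.join(out_dir, "surface_differences.csv"), index=False
        )
        self.regression_table.to_csv(
            os.path.join(out_dir, "consistency_regressions.csv"), index=False
        )


def _subject_spec(rng: np.random.Generator, extrusion: float, kl_grade: int) -> PhantomSpec:
    """Randomized anatomy around the canonical phantom; higher KL grades get
    marginal osteophytes, as in an osteoarthritic cohort."""
    r_med = 23.0 + rng.uniform(-1.5, 1.5)
    r_lat = 23.0 + rng.uniform(-1.5, 1.5)
    c = 17.0 + rng.uniform(-1.0, 1.0)
    osteo = None
    if kl_grade >= 2:
        osteo = OsteophyteSpec(
            angle_deg=rng.uniform(-20.0, 20.0),
            radial_mm=1.0 + 0.8 * kl_grade,
        )
    return PhantomSpec(
        condyle_radii=(r_med, r_lat),
        condyle_centers_z=(c, -c),
        shaft_length=55.0,
        meniscus=MeniscusSpec(extrusion_mm=extrusion),
        osteophyte=osteo,
        spine_ridge_x=float(rng.uniform(-4.0, 4.0)),
    )


def measure_subject(
    spec: PhantomSpec,
    seed: int,
    params: MeasurementParams = MeasurementParams(),
    icp_samples: int = 5000,
) -> dict:
    """One subject's full CT/MRI measurement set."""
    tibia, meniscus, truth = make_phantom(spec)
    ct_tibia = emulate_acquisition(tibia, "ct", seed=seed)
    mri_tibia = emulate_acquisition(tibia, "mri", seed=seed + 1)
    mri_meniscus = emulate_acquisition(meniscus, "mri", seed=seed + 2)

    notch = [0.0, spec.notch_level_y, 0.0]
    frame_ct = fit_tibial_frame(ct_tibia, notch_plane_point=notch)
    xform, icp_info = icp_register(
        ct_tibia, mri_tibia, n_samples=icp_samples, tol=1e-3, seed=seed, full_output=True
    )
    frame_mri = transfer_frame(frame_ct, xform)

    res_ct, sec_ct, plat_ct = measure_extrusion(ct_tibia, mri_meniscus, frame_ct, params)
    res_mri, sec_mri, plat_mri = measure_extrusion(
        mri_tibia, mri_meniscus, frame_mri, params
    )
    met_ct = plateau_metrics(plat_ct, sec_ct)
    met_mri = plateau_metrics(plat_mri, sec_mri)
    comp = signed_surface_difference(plat_ct, plat_mri, seed=seed)

    # conventional 2D width on the MRI tibia + meniscus
    local_tibia = frame_mri.mesh_to_frame(mri_tibia)
    local_men = frame_mri.mesh_to_frame(mri_meniscus)
    slice_x = select_coronal_slice(local_tibia, None, (0.2, 6.0, -10.0, 10.0))
    t_contours = coronal_contours(local_tibia, slice_x)
    m_contours = coronal_contours(local_men, slice_x)
    width2d = np.nan
    if t_contours and m_contours:
        tc = max(t_contours, key=len)
        mc = max(m_contours, key=lambda c: c[:, 1].max())
        band = tc[(tc[:, 0] > -8.0) & (tc[:, 0] < 1.0)]
        if len(band):
            ref = band[int(np.argmax(band[:, 1]))]
            width2d = compute_2d_width(tc, mc, ref).width
    return {
        "true_width": truth.width,
        "true_volume": truth.volume,
        "volume_ct": res_ct.volume,
        "volume_mri": res_mri.volume,
        "width_ct": res_ct.width,
        "width_mri": res_mri.width,
        "width_2d": width2d,
        "plateau_volume_ct": met_ct.volume,
        "plateau_volume_mri": met_mri.volume,
        "plateau_area_ct": met_ct.cross_sectional_area,
        "plateau_area_mri": met_mri.cross_sectional_area,
        "surface_diff_mean": comp.mean,
        "surface_diff_ci_low": comp.ci95_low,
        "surface_diff_ci_high": comp.ci95_high,
        "icp_rms": icp_info["rms"],
        "_comparison": comp,
    }


def _variable_row(name: str, ct: np.ndarray, mri: np.ndarray, n: int) -> dict:
    t = vs.two_sample_t(ct, mri)
    d = abs(t.cohens_d)
    row = {
        "variable": name,
        "ct_mean": ct.mean(),
        "ct_ci_low": ct.mean() - 1.96 * ct.std(ddof=1) / np.sqrt(n),
        "ct_ci_high": ct.mean() + 1.96 * ct.std(ddof=1) / np.sqrt(n),
        "ct_median": float(np.median(ct)),
        "ct_iqr": float(np.subtract(*np.percentile(ct, [75, 25]))),
        "ct_shapiro_p": vs.shapiro_wilk(ct)[1],
        "mri_mean": mri.mean(),
        "mri_ci_low": mri.mean() - 1.96 * mri.std(ddof=1) / np.sqrt(n),
        "mri_ci_high": mri.mean() + 1.96 * mri.std(ddof=1) / np.sqrt(n),
        "mri_median": float(np.median(mri)),
        "mri_iqr": float(np.subtract(*np.percentile(mri, [75, 25]))),
        "mri_shapiro_p": vs.shapiro_wilk(mri)[1],
        "p_value": t.p_value,
        "effect_size_d": d,
        "power": vs.achieved_power(max(d, 1e-6), n, test="two_sample"),
    }
    return row


def _regression_row(outcome: str, x_name: str, y_name: str, y, x) -> dict:
    r = vs.consistency_regression(y, x)
    return {
        "outcome": outcome,
        "independent": x_name,
        "dependent": y_name,
        "B": r.b,
        "se_B": r.se_b,
        "beta": r.beta,
        "t": r.t_stat,
        "p_value": r.p_value,
        "r2_adj": r.r2_adj,
        "F": r.f_stat,
        "df1": r.df[0],
        "df2": r.df[1],
    }


def run_cohort_study(
    n_subjects: int = 10,
    seed: int = 0,
    out_dir: str | None = None,
    params: MeasurementParams = MeasurementParams(),
) -> CohortReport:
    """Simulate the full agreement study and assemble its three tables."""
    if n_subjects < 3:
        raise ValueError("cohort needs at least 3 subjects")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_subjects)]
    rng = np.random.default_rng(ss.spawn(1)[0])
    extrusions = np.linspace(1.5, 6.5, n_subjects)
    kl_pattern = [1, 2, 3]
    records = []
    comparisons = []
    kl_grades = []
    for i in range(n_subjects):
        kl = kl_pattern[i % 3]
        spec = _subject_spec(rng, float(extrusions[i]), kl)
        rec = measure_subject(spec, seed=child_seeds[i], params=params)
        comparisons.append(rec.pop("_comparison"))
        rec["subject"] = i + 1
        rec["kl_grade"] = kl
        records.append(rec)
        kl_grades.append(kl)
    subjects = pd.DataFrame(records)

    n = n_subjects
    comparison_table = pd.DataFrame(
        [
            _variable_row(
                "plateau_volume_mm3",
                subjects["plateau_volume_ct"].to_numpy(),
                subjects["plateau_volume_mri"].to_numpy(),
                n,
            ),
            _variable_row(
                "plateau_area_mm2",
                subjects["plateau_area_ct"].to_numpy(),
                subjects["plateau_area_mri"].to_numpy(),
                n,
            ),
            _variable_row(
                "mme_volume_mm3",
                subjects["volume_ct"].to_numpy(),
                subjects["volume_mri"].to_numpy(),
                n,
            ),
            _variable_row(
                "mme_width_mm",
                subjects["width_ct"].to_numpy(),
                subjects["width_mri"].to_numpy(),
                n,
            ),
        ]
    )

    summary = cohort_summary(comparisons, labels=[str(i + 1) for i in range(n)])
    surface_table = summary.table
    surface_table.insert(1, "kl_grade", kl_grades)

    regression_table = pd.DataFrame(
        [
            _regression_row(
                "plateau_volume",
                "mri",
                "ct",
                subjects["plateau_volume_ct"],
                subjects["plateau_volume_mri"],
            ),
            _regression_row(
                "plateau_area",
                "mri",
                "ct",
                subjects["plateau_area_ct"],
                subjects["plateau_area_mri"],
            ),
            _regression_row(
                "mme_volume", "mri", "ct", subjects["volume_ct"], subjects["volume_mri"]
            ),
            _regression_row(
                "mme_width", "mri", "ct", subjects["width_ct"], subjects["width_mri"]
            ),
            _regression_row(
                "mme_width_2d_vs_3d",
                "width_3d",
                "width_2d",
                subjects["width_2d"],
                subjects["width_mri"],
            ),
        ]
    )
    report = CohortReport(
        subjects=subjects,
        comparison_table=comparison_table,
        surface_table=surface_table,
        regression_table=regression_table,
        surface_min_mean=summary.minimal.mean,
        surface_max_mean=summary.maximal.mean,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
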