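"""Mixed beam model: per-voxel LQM mixing, biological/clinical dose, survival.

Each pencil beam deposits dose with its own linear-quadratic parameters
alpha_ij, beta_ij (functions of the local dose-averaged LET). The mixed beam
model forms per-voxel parameters as dose-weighted means over all beams,

    alpha_i = (1/d_i) sum_j alpha_ij d_ij x_j,
    beta_i  = (1/d_i) sum_j beta_ij  d_ij x_j,

so the biological effect is e_i = alpha_i d_i + beta_i d_i^2, which equals
the bilinear form a_i + b_i d_i with a_i = sum_j alpha_ij d_ij x_j and
b_i = sum_j beta_ij d_ij x_j. The photon-equivalent (biological) dose
inverts the photon LQM at equal effect, and the clinical dose in Gy(RBE) is
the biological dose times a fixed clinical factor. Surviving fraction is
SF = exp(-e).

Default photon constants are the standard HSG values alpha_X = 0.313 /Gy,
beta_X = 0.0615 /Gy^2; the clinical factor 1.442 is calibrated so that a
clinical dose of 5.88 Gy(RBE) sits at the photon 10%-survival level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .influence import InfluenceSet

__all__ = [
    "PhotonLQM",
    "MixedEffectFields",
    "photon_effect",
    "biological_dose",
    "clinical_dose",
    "clinical_to_biological",
    "prescription_effect",
    "surviving_fraction",
    "mixed_effect",
    "effect_from_components",
    "flask_sf",
]


@dataclass(frozen=True)
class PhotonLQM:
    """Photon reference LQM parameters plus the Gy(RBE) clinical factor."""

    alpha_x: float = 0.313   # 1/Gy
    beta_x: float = 0.0615   # 1/Gy^2
    clinical_factor: float = 1.442

    def __post_init__(self) -> None:
        if self.alpha_x <= 0 or self.beta_x <= 0 or self.clinical_factor <= 0:
            raise ValueError("photon LQM parameters must be positive")


def photon_effect(dose: np.ndarray | float, lqm: PhotonLQM) -> np.ndarray | float:
    d = np.asarray(dose, dtype=float)
    e = lqm.alpha_x * d + lqm.beta_x * d**2
    return float(e) if np.isscalar(dose) else e


def biological_dose(effect: np.ndarray | float, lqm: PhotonLQM) -> np.ndarray | float:
    """Photon-equivalent dose: positive root of alpha_X d + beta_X d^2 = e."""
    e = np.asarray(effect, dtype=float)
    if np.any(e < 0):
        raise ValueError("biological effect must be nonnegative")
    d = (np.sqrt(lqm.alpha_x**2 + 4.0 * lqm.beta_x * e) - lqm.alpha_x) / (
        2.0 * lqm.beta_x
    )
    return float(d) if np.isscalar(effect) else d


def clinical_dose(d_bio: np.ndarray | float, lqm: PhotonLQM) -> np.ndarray | float:
    if np.any(np.asarray(d_bio) < 0):
        raise ValueError("biological dose must be nonnegative")
    out = np.asarray(d_bio, dtype=float) * lqm.clinical_factor
    return float(out) if np.isscalar(d_bio) else out


def clinical_to_biological(d_clin: np.ndarray | float,
                           lqm: PhotonLQM) -> np.ndarray | float:
    out = np.asarray(d_clin, dtype=float) / lqm.clinical_factor
    return float(out) if np.isscalar(d_clin) else out


def prescription_effect(d_clin_gyrbe: float, lqm: PhotonLQM) -> float:
    """Biological effect corresponding to a clinical prescription dose."""
    return float(photon_effect(clinical_to_biological(d_clin_gyrbe, lqm), lqm))


def surviving_fraction(effect: np.ndarray | float) -> np.ndarray | float:
    e = np.asarray(effect, dtype=float)
    if np.any(e < 0):
        raise ValueError("biological effect must be nonnegative")
    sf = np.exp(-e)
    return float(sf) if np.isscalar(effect) else sf


@dataclass
class MixedEffectFields:
    """Per-voxel mixed-field quantities on the calculation voxel list."""

    voxel_idx: np.ndarray        # linear grid indices of the calculation voxels
    alpha: np.ndarray            # mixed alpha_i (1/Gy)
    beta: np.ndarray             # mixed beta_i (1/Gy^2)
    dose: np.ndarray             # physical dose d_i (Gy)
    effect: np.ndarray           # e_i (dimensionless)
    lqm: PhotonLQM

    @property
    def biological(self) -> np.ndarray:
        return biological_dose(self.effect, self.lqm)

    @property
    def clinical(self) -> np.ndarray:
        return clinical_dose(self.biological, self.lqm)

    @property
    def rbe(self) -> np.ndarray:
        """Biological over physical dose where dose is nonzero, else 1."""
        out = np.ones_like(self.dose)
        nz = self.dose > 0
        out[nz] = self.biological[nz] / self.dose[nz]
        return out


def effect_from_components(a: np.ndarray, b: np.ndarray,
                           d: np.ndarray) -> np.ndarray:
    """e = a + b d, the bilinear form of the mixed-field LQM effect."""
    return a + b * d


def mixed_effect(infl: "InfluenceSet", x: np.ndarray,
                 lqm: PhotonLQM | None = None,
                 beta_mixing: str = "linear") -> MixedEffectFields:
    """Mixed-field quantities for spot weights ``x`` over all fields.

    Voxels with zero physical dose get alpha = beta = effect = 0.
    ``beta_mixing`` selects how beta mixes across components: ``"linear"``
    (dose-weighted mean of beta, the default) or ``"sqrt"`` (dose-weighted
    mean of sqrt(beta), squared — the classical mixed-field convention),
    available for sensitivity checks.
    """
    lqm = lqm or PhotonLQM()
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("spot weights must be nonnegative")
    if beta_mixing not in ("linear", "sqrt"):
        raise ValueError("beta_mixing must be 'linear' or 'sqrt'")
    d, a, b = infl.dab(x)
    nz = d > 0
    alpha = np.zeros_like(d)
    beta = np.zeros_like(d)
    alpha[nz] = a[nz] / d[nz]
    if beta_mixing == "sqrt":
        # sum_j sqrt(beta_ij) d_ij x_j from the stored beta_ij d_ij entries:
        # sqrt(beta d) * sqrt(d) = sqrt((B elementwise* D)) elementwise
        sb = np.zeros_like(d)
        for fid, (D, A, B) in infl.per_field.items():
            C = B.multiply(D).sqrt()
            sb += C @ x[infl.field_cols[fid]]
        beta[nz] = (sb[nz] / d[nz]) ** 2
        b = beta * d
    else:
        beta[nz] = b[nz] / d[nz]
    return MixedEffectFields(
        voxel_idx=infl.voxel_idx,
        alpha=alpha,
        beta=beta,
        dose=d,
        effect=effect_from_components(a, b, d),
        lqm=lqm,
    )


def flask_sf(fields: MixedEffectFields, flask_rows: np.ndarray) -> float:
    """Survival-weighted mean SF over a flask: mean over voxels of exp(-e)."""
    rows = np.asarray(flask_rows)
    if rows.size == 0:
        raise ValueError("flask mask selects no calculation voxels")
    return float(np.mean(np.exp(-fields.effect[rows])))
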