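"""Semi-empirical photo-assimilation performance index (I_PL).

I_PL is a fast proxy for net leaf photosynthesis (A_n) built from light-adapted
chlorophyll fluorescence and leaf temperature, usable at ~30 s per leaf:

    PhiPSII  = (Fm' - Fs) / Fm'                     effective PSII efficiency
    J_PSII   = PhiPSII * PPFD * absorptance * f_PSII   electron transport rate
    P_KO/KC  = J_PSII * K_O(T_leaf) / K_C(T_leaf)
    I_PL     = b0 + b1 * P_KO/KC + b2 * (T_leaf - T_air)

The K_O/K_C ratio folds the temperature dependence of RuBisCO oxygenation vs
carboxylation into the electron-transport signal.  The three coefficients are
calibrated per gas-exchange device against IRGA-measured A_n on a random 2/3
of the records and validated on the held-out 1/3; device-specific coefficients
matter because each unit's internal fluorescence calibration shifts the
predictor scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "IplConstants",
    "IplModel",
    "phi_psii",
    "j_psii",
    "ko_kc_ratio",
    "prepare_predictors",
    "calibrate_ipl",
    "predict_ipl",
]

R_GAS = 8.314  # J mol-1 K-1
T_REF_K = 298.15


@dataclass(frozen=True)
class IplConstants:
    """Physical constants feeding the I_PL predictors.

    ``absorptance`` (leaf absorptance of incident PPFD) and ``f_psii``
    (fraction of absorbed quanta routed to PSII) are the widely used leaf-level
    defaults.  The K_O/K_C temperature response is an Arrhenius form with the
    standard in-vivo reference constants and activation energies; the ratio is
    taken on the constants' native printed units (K_O in mmol mol-1, K_C in
    umol mol-1), a fixed scale absorbed by the linear calibration.  Setting
    ``constant_ratio`` bypasses the temperature response entirely.
    """

    absorptance: float = 0.84
    f_psii: float = 0.5
    kc25: float = 404.9  # umol mol-1
    ea_kc: float = 79430.0  # J mol-1
    ko25: float = 278.4  # mmol mol-1
    ea_ko: float = 36380.0  # J mol-1
    constant_ratio: float | None = None


DEFAULT_CONSTANTS = IplConstants()


def phi_psii(fs, fm_prime):
    """Effective PSII quantum efficiency, (Fm' - Fs)/Fm', in [0, 1]."""
    fs = np.asarray(fs, dtype=float)
    fm = np.asarray(fm_prime, dtype=float)
    if np.any(fm <= 0):
        raise ValueError("Fm' must be > 0")
    if np.any(fs < 0) or np.any(fs > fm):
        raise ValueError("need 0 <= Fs <= Fm'")
    out = (fm - fs) / fm
    return float(out) if out.ndim == 0 else out


def j_psii(phi, ppfd, absorptance: float = 0.84, f_psii: float = 0.5):
    """Electron transport rate exiting PSII, umol m-2 s-1:
    J_PSII = PhiPSII * PPFD * absorptance * f_PSII."""
    phi = np.asarray(phi, dtype=float)
    ppfd = np.asarray(ppfd, dtype=float)
    if np.any(phi < 0) or np.any(ppfd < 0):
        raise ValueError("PhiPSII and PPFD must be >= 0")
    out = phi * ppfd * absorptance * f_psii
    return float(out) if out.ndim == 0 else out


def ko_kc_ratio(t_leaf, constants: IplConstants = DEFAULT_CONSTANTS):
    """Ratio of the RuBisCO Michaelis constants K_O / K_C at leaf temperature
    (deg C), from Arrhenius temperature responses of each constant.

    Since the activation energy of K_C exceeds that of K_O, the ratio falls
    with temperature.  Temperatures outside 0-50 deg C are extrapolated with a
    warning.  ``constants.constant_ratio`` short-circuits to a fixed value.
    """
    t_leaf = np.asarray(t_leaf, dtype=float)
    if constants.constant_ratio is not None:
        out = np.full_like(t_leaf, float(constants.constant_ratio))
        return float(out) if out.ndim == 0 else out
    if np.any((t_leaf < 0) | (t_leaf > 50)):
        import warnings

        warnings.warn(
            "leaf temperature outside 0-50 degC: extrapolating the Arrhenius response",
            RuntimeWarning,
            stacklevel=2,
        )
    tk = t_leaf + 273.15
    arrh = np.exp((constants.ea_ko - constants.ea_kc) * (tk - T_REF_K) / (R_GAS * T_REF_K * tk))
    out = (constants.ko25 / constants.kc25) * arrh
    return float(out) if out.ndim == 0 else out


def prepare_predictors(records: pd.DataFrame, constants: IplConstants = DEFAULT_CONSTANTS):
    """Derive the two I_PL predictors from raw fluorescence records.

    Expects columns Fs, Fm_prime, PPFD, T_leaf, T_air; returns a copy with
    phi_psii, j_psii, p_kokc and dT (= T_leaf - T_air) columns appended.
    """
    out = records.copy()
    phi = phi_psii(out["Fs"].to_numpy(), out["Fm_prime"].to_numpy())
    j = j_psii(phi, out["PPFD"].to_numpy(), constants.absorptance, constants.f_psii)
    out["phi_psii"] = phi
    out["j_psii"] = j
    out["p_kokc"] = j * ko_kc_ratio(out["T_leaf"].to_numpy(), constants)
    out["dT"] = out["T_leaf"] - out["T_air"]
    return out


@dataclass
class IplModel:
    """Per-device calibrated I_PL model with its validation metrics."""

    device: str
    beta0: float
    beta1: float  # P_KO/KC
    beta2: float  # T_leaf - T_air
    r2_calibration: float
    r2_validation: float
    rmse_validation: float
    n_calibration: int
    n_validation: int
    p_values: dict = field(default_factory=dict)
    conf_int: dict = field(default_factory=dict)
    seed: int | None = None
    constants: IplConstants = DEFAULT_CONSTANTS

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "IplModel":
        d = dict(d)
        d["constants"] = IplConstants(**d["constants"])
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "IplModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _r2(obs, pred) -> float:
    if len(obs) < 2 or np.std(obs) == 0 or np.std(pred) == 0:
        return float("nan")
    return float(np.corrcoef(obs, pred)[0, 1] ** 2)


def calibrate_ipl(
    records: pd.DataFrame,
    split_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    constants: IplConstants = DEFAULT_CONSTANTS,
    device_col: str = "device",
    stratify_by: str | None = None,
    return_split: bool = False,
):
    """Per-device calibration of I_PL against measured A_n.

    For each device: a seeded random ``split_fraction`` of records (default
    2/3) fits an OLS of A_n on P_KO/KC and (T_leaf - T_air) with intercept;
    the held-out remainder yields validation R2 (squared Pearson correlation
    between observed and predicted) and RMSE in A_n units.  Records with
    missing A_n are excluded (count kept in the model's metadata via n_*).
    ``stratify_by`` names a column (e.g. the daytime period) within whose
    levels the split is drawn, keeping both sets balanced across levels.

    Returns a dict device id -> :class:`IplModel`; with ``return_split=True``
    also a table assigning every record to its calibration/validation role,
    so set disjointness can be audited.
    """
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must lie strictly between 0 and 1")
    data = prepare_predictors(records, constants)
    data = data[np.isfinite(data["An"])].copy()
    rng = np.random.default_rng(seed)
    models = {}
    split_rows = []
    for device, grp in data.groupby(device_col, sort=True):
        n = len(grp)
        if n < 10:
            raise ValueError(
                f"device {device!r}: {n} records with A_n < 10 required for calibration"
            )
        if np.ptp(grp["p_kokc"].to_numpy()) == 0 or np.ptp(grp["dT"].to_numpy()) == 0:
            raise ValueError(f"device {device!r}: constant predictor, rank-deficient design")
        if stratify_by is not None:
            cal_idx = []
            for _, stratum in grp.groupby(stratify_by, sort=True):
                sperm = rng.permutation(len(stratum))
                k = int(round(len(stratum) * split_fraction))
                cal_idx.extend(stratum.index[sperm[:k]])
            cal = grp.loc[grp.index.isin(cal_idx)]
            val = grp.loc[~grp.index.isin(cal_idx)]
            if len(cal) < 3 or len(val) < 1:
                raise ValueError(f"device {device!r}: stratified split leaves too few records")
            n_cal = len(cal)
        else:
            perm = rng.permutation(n)
            n_cal = int(round(n * split_fraction))
            n_cal = min(max(n_cal, 3), n - 1)
            cal = grp.iloc[perm[:n_cal]]
            val = grp.iloc[perm[n_cal:]]
        split_rows.extend(
            {"device": device, "record": idx, "role": role}
            for role, part in (("calibration", cal), ("validation", val))
            for idx in part.index
        )
        X = sm.add_constant(cal[["p_kokc", "dT"]].to_numpy())
        fit = sm.OLS(cal["An"].to_numpy(), X).fit()
        b0, b1, b2 = fit.params
        Xv = sm.add_constant(val[["p_kokc", "dT"]].to_numpy(), has_constant="add")
        pred_val = Xv @ fit.params
        rmse = float(np.sqrt(np.mean((val["An"].to_numpy() - pred_val) ** 2)))
        ci = fit.conf_int(alpha=0.05)
        models[device] = IplModel(
            device=str(device),
            beta0=float(b0),
            beta1=float(b1),
            beta2=float(b2),
            r2_calibration=_r2(cal["An"].to_numpy(), fit.fittedvalues),
            r2_validation=_r2(val["An"].to_numpy(), pred_val),
            rmse_validation=rmse,
            n_calibration=int(n_cal),
            n_validation=int(n - n_cal),
            p_values={
                "intercept": float(fit.pvalues[0]),
                "p_kokc": float(fit.pvalues[1]),
                "dT": float(fit.pvalues[2]),
            },
            conf_int={
                "p_kokc": [float(ci[1, 0]), float(ci[1, 1])],
                "dT": [float(ci[2, 0]), float(ci[2, 1])],
            },
            seed=seed,
            constants=constants,
        )
    if return_split:
        return models, pd.DataFrame(split_rows)
    return models


def predict_ipl(
    model: IplModel, records: pd.DataFrame, device_col: str = "device"
) -> np.ndarray:
    """High-throughput I_PL per record from a calibrated model:
    I_PL = b0 + b1 * P_KO/KC + b2 * (T_leaf - T_air).

    All records must belong to the model's device (device-specific internal
    calibrations make coefficients non-transferable).
    """
    if device_col in records.columns:
        devices = set(records[device_col].astype(str).unique())
        if devices - {model.device}:
            raise ValueError(
                f"records from device(s) {sorted(devices - {model.device})} "
                f"passed to the model for device {model.device!r}"
            )
    data = prepare_predictors(records, model.constants)
    return (
        model.beta0 + model.beta1 * data["p_kokc"].to_numpy() + model.beta2 * data["dT"].to_numpy()
    )
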