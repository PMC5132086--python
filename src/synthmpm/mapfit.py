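"""Quantitative map estimation from weighted volumes.

The chain mirrors a standard MPM reconstruction: R2* from a log-linear fit
of the PD-weighted multi-echo decay; echo averaging for SNR; transmit-field
mapping from SE/STE pairs; apparent R1 and PD* from the dual-flip-angle
rational approximation of the Ernst equation with B1 correction and an
optional imperfect-spoiling correction; and the semi-quantitative MT
saturation from the MT-weighted amplitude.
"""

from __future__ import annotations

import numpy as np

from .flash import (AcquisitionProtocol, SpoilingCorrection, effective_flip,
                    rational_r1_pdstar)
from .volumes import (QuantitativeMap, TransmitFieldMap, WeightedVolume,
                      check_aligned)

__all__ = [
    "average_echoes",
    "compute_mtsat",
    "compute_r1_pdstar",
    "correct_mtsat_b1",
    "fit_maps",
    "fit_r2star",
    "map_transmit_field",
]


def fit_r2star(volume: WeightedVolume, mask=None) -> QuantitativeMap:
    """Voxel-wise mono-exponential R2* from the multi-echo decay.

    Ordinary least squares of ln(signal) against TE; R2* is the negated
    slope and ln(S0) (the TE=0 intercept) is kept in ``aux["ln_s0"]``.
    Voxels with any non-positive echo signal are flagged invalid rather than
    fitted.  Negative fitted R2* values are retained (flagged via
    ``aux["negative"]``), never clamped, so noise statistics stay unbiased.
    """
    if volume.n_echoes < 3:
        raise ValueError("R2* fit needs at least 3 echoes")
    te = np.asarray(volume.te_s)
    signals = volume.echoes
    grid = volume.grid_shape

    positive = np.all(signals > 0, axis=0)
    valid = positive if mask is None else (positive & np.asarray(mask, dtype=bool))

    flat = signals.reshape(volume.n_echoes, -1)
    sel = valid.ravel()
    design = np.column_stack([np.ones_like(te), -te])
    r2star = np.full(flat.shape[1], np.nan)
    ln_s0 = np.full(flat.shape[1], np.nan)
    if sel.any():
        coef, *_ = np.linalg.lstsq(design, np.log(flat[:, sel]), rcond=None)
        ln_s0[sel] = coef[0]
        r2star[sel] = coef[1]
    r2star = r2star.reshape(grid)
    ln_s0 = ln_s0.reshape(grid)
    return QuantitativeMap(r2star, kind="R2star", provenance="measured",
                           aux={"valid": valid, "ln_s0": ln_s0,
                                "negative": valid & (r2star < 0)})


def average_echoes(volume: WeightedVolume, n_echoes: int = 6) -> np.ndarray:
    """Arithmetic mean of the first ``n_echoes`` echo images (SNR boost)."""
    if volume.n_echoes < n_echoes:
        raise ValueError(f"volume has {volume.n_echoes} echoes, need {n_echoes}")
    return volume.echoes[:n_echoes].mean(axis=0)


def map_transmit_field(se_images, ste_images, nominal_rad,
                       clamp_tol: float = 0.02) -> TransmitFieldMap:
    """Transmit efficiency from spin-echo / stimulated-echo image pairs.

    Per pair, the achieved flip angle is arccos(STE/SE); the per-voxel
    efficiency is the least-squares slope (through the origin) of achieved
    vs nominal angle over all valid pairs.  Ratios outside [-1, 1] by more
    than ``clamp_tol`` invalidate the pair at that voxel; ratios within the
    tolerance band are clamped (noise on a ratio near +/-1).
    """
    if len(se_images) != len(ste_images) or len(se_images) != len(nominal_rad):
        raise ValueError("need one SE image, one STE image per nominal angle")
    nominal_rad = np.asarray(nominal_rad, dtype=float)
    if np.any((nominal_rad <= 0) | (nominal_rad >= np.pi)):
        raise ValueError("nominal angles must lie in (0, pi)")
    grid = check_aligned(*se_images, *ste_images)

    num = np.zeros(grid)
    den = np.zeros(grid)
    n_valid = np.zeros(grid, dtype=int)
    for se, ste, nom in zip(se_images, ste_images, nominal_rad):
        se = np.asarray(se, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.asarray(ste, dtype=float) / se
        ok = (se > 0) & np.isfinite(ratio) & (np.abs(ratio) <= 1.0 + clamp_tol)
        achieved = np.arccos(np.clip(ratio, -1.0, 1.0))
        num += np.where(ok, achieved * nom, 0.0)
        den += np.where(ok, nom ** 2, 0.0)
        n_valid += ok
    valid = n_valid > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        efficiency = np.where(valid, num / den, np.nan)
    valid &= efficiency > 0
    return TransmitFieldMap(efficiency=np.where(valid, efficiency, np.nan),
                            valid=valid)


def compute_r1_pdstar(avg_pd, avg_t1, protocol: AcquisitionProtocol,
                      b1: TransmitFieldMap,
                      spoiling: SpoilingCorrection = None):
    """Apparent R1 and PD* from the echo-averaged PD- and T1-weighted images.

    Flip angles are corrected voxel-wise by the transmit efficiency before
    the rational inversion; the apparent T1 is then passed through the
    imperfect-spoiling correction (identity if ``spoiling`` is None).
    Degenerate voxels (signal ratios carrying no T1 information) and voxels
    with an invalid B1 estimate are flagged, not silently filled.
    """
    spoiling = spoiling or SpoilingCorrection.identity()
    avg_pd = np.asarray(avg_pd, dtype=float)
    avg_t1 = np.asarray(avg_t1, dtype=float)
    check_aligned(avg_pd, avg_t1, b1.efficiency)

    eff = np.where(b1.valid, b1.efficiency, np.nan)
    a_pd = eff * protocol.pd.flip_rad
    a_t1 = eff * protocol.t1.flip_rad
    r1_app, pd_star, nondegenerate = rational_r1_pdstar(
        avg_pd, avg_t1, a_pd, a_t1, protocol.pd.tr_s, protocol.t1.tr_s)
    valid = nondegenerate & b1.valid & np.isfinite(r1_app) & (r1_app != 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t1_app = 1.0 / r1_app
        t1_corr = spoiling.correct_t1(t1_app, np.where(b1.valid, eff, 1.0))
        r1 = np.where(valid & (t1_corr != 0), 1.0 / t1_corr, np.nan)
    r1_map = QuantitativeMap(r1, kind="R1", provenance="measured",
                             aux={"valid": valid & np.isfinite(r1),
                                  "negative": valid & (r1 < 0)})
    pd_map = QuantitativeMap(np.where(valid, pd_star, np.nan), kind="PDstar",
                             provenance="measured",
                             aux={"valid": valid & np.isfinite(pd_star)})
    return r1_map, pd_map


def compute_mtsat(avg_mt, pdstar: QuantitativeMap, r1: QuantitativeMap,
                  protocol: AcquisitionProtocol,
                  b1: TransmitFieldMap) -> QuantitativeMap:
    """Semi-quantitative MT saturation (percent units) from the MT-weighted
    amplitude.

    delta = (PD* * eps_c / S_MT - 1) * R1 * TR_MT - eps_c^2 / 2, with
    eps_c the B1-corrected effective flip angle of the MT-weighted
    excitation; the result is scaled by 100 into percent units.  Accounts
    for the spatially varying R1 and flip angle; voxels with non-positive
    MT-weighted signal are flagged.
    """
    avg_mt = np.asarray(avg_mt, dtype=float)
    check_aligned(avg_mt, pdstar.values, r1.values, b1.efficiency)
    eff = np.where(b1.valid, b1.efficiency, np.nan)
    eps = effective_flip(eff * protocol.mt.flip_rad)
    valid = (avg_mt > 0) & pdstar.valid & r1.valid & b1.valid
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = ((pdstar.values * eps / avg_mt - 1.0) * r1.values
                 * protocol.mt.tr_s - eps ** 2 / 2.0)
    return QuantitativeMap(np.where(valid, 100.0 * delta, np.nan), kind="MTsat",
                           provenance="measured",
                           aux={"valid": valid & np.isfinite(delta)})


def correct_mtsat_b1(mtsat: QuantitativeMap, b1: TransmitFieldMap,
                     C: float = 0.4) -> QuantitativeMap:
    """Empirical correction of residual flip-angle dependence of MT saturation.

    corrected = mtsat * (1 - C) / (1 - C * efficiency); C = 0.4 is a
    configurable empirical constant appropriate at 3 T.  C = 0 or a uniform
    unit efficiency leave the map unchanged.
    """
    if not 0 <= C < 1:
        raise ValueError("C must lie in [0, 1)")
    check_aligned(mtsat.values, b1.efficiency)
    scale = (1.0 - C) / (1.0 - C * b1.efficiency)
    return QuantitativeMap(mtsat.values * scale, kind="MTsat",
                           provenance=mtsat.provenance,
                           aux={"valid": mtsat.valid & b1.valid})


def _decay_compensation(te_s, r2star_values):
    """Mean R2* decay factor of the averaged echoes, for TE=0 extrapolation."""
    te = np.asarray(te_s)[:, None, None, None]
    return np.exp(-te * r2star_values[None]).mean(axis=0)


def fit_maps(session, spoiling: SpoilingCorrection = None, n_avg_echoes: int = 6,
             b1_correction_c: float = 0.0, decay_correction: bool = True) -> dict:
    """Run the full map-estimation chain on an MPM session.

    Returns a dict with keys ``r2star``, ``r1``, ``pdstar``, ``mtsat``
    (:class:`QuantitativeMap`) and ``b1`` (:class:`TransmitFieldMap`).
    ``b1_correction_c`` > 0 additionally applies :func:`correct_mtsat_b1`.

    With ``decay_correction`` (default) the echo-averaged images are divided
    by the mean R2* decay factor of the averaged echoes (from the fitted
    R2*), referring them to TE = 0.  The factor is common to all three
    contrasts (shared echo times), so R1 and MT saturation are unaffected;
    PD* becomes the TE = 0 amplitude rather than an echo-time-weighted one.
    """
    protocol = session.protocol
    r2star = fit_r2star(session.pd_w)
    avg_pd = average_echoes(session.pd_w, n_avg_echoes)
    avg_t1 = average_echoes(session.t1_w, n_avg_echoes)
    avg_mt = average_echoes(session.mt_w, n_avg_echoes)
    if decay_correction:
        with np.errstate(invalid="ignore"):
            decay = _decay_compensation(session.pd_w.te_s[:n_avg_echoes],
                                        r2star.values)
            avg_pd = avg_pd / decay
            avg_t1 = avg_t1 / decay
            avg_mt = avg_mt / decay
    b1 = map_transmit_field(session.se_images, session.ste_images,
                            session.b1_nominal_rad)
    r1, pdstar = compute_r1_pdstar(avg_pd, avg_t1, protocol, b1, spoiling)
    mtsat = compute_mtsat(avg_mt, pdstar, r1, protocol, b1)
    if b1_correction_c:
        mtsat = correct_mtsat_b1(mtsat, b1, C=b1_correction_c)
    return {"r2star": r2star, "r1": r1, "pdstar": pdstar, "mtsat": mtsat, "b1": b1}
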