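"""Realism statistics and rater-study scoring for image sets.

Four statistics compare a set of real(istic) images with a generated set:
per-channel RGB intensity histograms, the radially averaged power spectrum,
per-image mean saturation vs mean luminance, and a Fréchet distance between
Gaussian fits of image features.  The default feature extractor is fully
self-contained (colour moments plus radial spectral band powers), so no
pretrained network is required; an external deep-feature extractor can be
plugged in through the ``extractor`` argument for conventional FID.

Also provided: scoring of blinded real-vs-generated assessments, per-group
severity score summaries (mean +- SEM), and the erythema index used as a
severity proxy throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "RealismReport",
    "rgb_histograms",
    "radial_power_spectrum",
    "radial_bin_counts",
    "saturation_luminance",
    "frechet_feature_distance",
    "default_features",
    "score_assessment",
    "summarize_scores",
    "erythema_index",
    "realism_report",
]

GRAY_WEIGHTS = (0.299, 0.587, 0.114)


def _check_images(images: Sequence[np.ndarray]) -> None:
    if len(images) == 0:
        raise ValueError("empty image set")


def erythema_index(image: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean redness R - (G+B)/2 over ``mask`` (whole image when mask is None).

    The severity proxy for monotonicity checks: redder plaques score higher;
    achromatic shifts (illumination, speckle, hair) leave it unchanged.
    """
    x = image.astype(np.float64)
    redness = x[..., 0] - 0.5 * (x[..., 1] + x[..., 2])
    if mask is None:
        return float(redness.mean())
    if not mask.any():
        raise ValueError("empty mask")
    return float(redness[mask].mean())


def rgb_histograms(images: Sequence[np.ndarray]) -> np.ndarray:
    """Pooled 256-bin intensity counts per channel, shape (3, 256)."""
    _check_images(images)
    out = np.zeros((3, 256), dtype=np.int64)
    for img in images:
        for c in range(3):
            out[c] += np.bincount(img[..., c].ravel(), minlength=256)
    return out


def _grayscale(image: np.ndarray) -> np.ndarray:
    x = image.astype(np.float64)
    return GRAY_WEIGHTS[0] * x[..., 0] + GRAY_WEIGHTS[1] * x[..., 1] + GRAY_WEIGHTS[2] * x[..., 2]


def radial_power_spectrum(
    images: Sequence[np.ndarray], truncate: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged 2-D power spectrum, averaged over the image set.

    Per image: grayscale conversion, unitary-normalised 2-D DFT, squared
    magnitude, binned by integer radial frequency from the spectrum centre.
    Bin 0 is the DC term.  With ``truncate`` the profile stops at the Nyquist
    radius N//2; otherwise corner frequencies are kept so that the summed
    power satisfies Parseval's identity with the pixel-domain energy.

    Returns (frequencies, mean power per bin).
    """
    _check_images(images)
    n = images[0].shape[0]
    if images[0].shape[0] != images[0].shape[1]:
        raise ValueError("radial_power_spectrum requires square images")
    fr = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / n))
    rr, cc = np.meshgrid(fr, fr, indexing="ij")
    radius = np.rint(np.hypot(rr, cc)).astype(int)
    r_max = radius.max() if not truncate else n // 2
    acc = np.zeros(r_max + 1, dtype=np.float64)
    counts = np.bincount(radius.ravel(), minlength=radius.max() + 1)
    for img in images:
        if img.shape[0] != n or img.shape[0] != img.shape[1]:
            raise ValueError("image set must be uniform and square")
        f = np.fft.fftshift(np.fft.fft2(_grayscale(img))) / n  # unitary norm
        power = np.bincount(radius.ravel(), weights=(np.abs(f) ** 2).ravel(),
                            minlength=radius.max() + 1)
        acc += power[: r_max + 1]
    mean_power = acc / (len(images) * np.maximum(counts[: r_max + 1], 1))
    # report summed power per radial bin averaged over images, normalised per
    # bin population so flat-noise spectra are flat
    return np.arange(r_max + 1), mean_power


def radial_bin_counts(n: int, truncate: bool = True) -> np.ndarray:
    """Pixel population of each integer-radius bin for an n x n spectrum.

    Multiplying the mean-power profile by these counts recovers the summed
    power per bin (used e.g. for Parseval bookkeeping).
    """
    fr = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / n))
    rr, cc = np.meshgrid(fr, fr, indexing="ij")
    radius = np.rint(np.hypot(rr, cc)).astype(int)
    counts = np.bincount(radius.ravel())
    return counts[: n // 2 + 1] if truncate else counts


def saturation_luminance(images: Sequence[np.ndarray]) -> np.ndarray:
    """Per-image (mean HSV saturation, mean HSV value), both in [0, 1]."""
    _check_images(images)
    out = np.empty((len(images), 2), dtype=np.float64)
    for i, img in enumerate(images):
        x = img.astype(np.float64) / 255.0
        v = x.max(axis=-1)
        mn = x.min(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(v > 0, (v - mn) / v, 0.0)
        out[i] = s.mean(), v.mean()
    return out


def default_features(images: Sequence[np.ndarray]) -> np.ndarray:
    """Self-contained per-image feature vector for the Fréchet distance.

    Per-channel mean and standard deviation (6), mean saturation and mean
    luminance (2), and log power in 8 radial frequency bands (8): 16 dims.
    """
    _check_images(images)
    n = images[0].shape[0]
    fr = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / n))
    rr, cc = np.meshgrid(fr, fr, indexing="ij")
    radius = np.rint(np.hypot(rr, cc)).astype(int)
    nyq = n // 2
    band_edges = np.unique(np.rint(np.geomspace(1, nyq + 1, 9)).astype(int))
    while len(band_edges) < 9:  # tiny images: pad edges
        band_edges = np.append(band_edges, band_edges[-1] + 1)
    feats = np.empty((len(images), 16), dtype=np.float64)
    for i, img in enumerate(images):
        x = img.astype(np.float64)
        feats[i, 0:3] = x.mean(axis=(0, 1))
        feats[i, 3:6] = x.std(axis=(0, 1))
        sl = saturation_luminance([img])[0]
        feats[i, 6:8] = sl
        f = np.abs(np.fft.fftshift(np.fft.fft2(_grayscale(img))) / n) ** 2
        for b in range(8):
            lo, hi = band_edges[b], band_edges[b + 1]
            sel = (radius >= lo) & (radius < hi)
            feats[i, 8 + b] = np.log10(f[sel].mean() + 1e-12)
    return feats


def frechet_feature_distance(
    set_a: Sequence[np.ndarray],
    set_b: Sequence[np.ndarray],
    extractor: Callable[[Sequence[np.ndarray]], np.ndarray] = default_features,
) -> float:
    """Fréchet distance between Gaussian fits of extracted features.

    d^2 = ||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2}); symmetric and
    zero when the two feature distributions coincide.  Near-singular
    covariances are shrunk by eps*I with eps = 1e-6 * trace(S)/dim.
    """
    fa = np.asarray(extractor(set_a), dtype=np.float64)
    fb = np.asarray(extractor(set_b), dtype=np.float64)
    return frechet_from_features(fa, fb)


def frechet_from_features(fa: np.ndarray, fb: np.ndarray) -> float:
    """Fréchet distance from raw per-sample feature matrices (n x d)."""
    mu_a, mu_b = fa.mean(axis=0), fb.mean(axis=0)
    cov_a = np.atleast_2d(np.cov(fa, rowvar=False))
    cov_b = np.atleast_2d(np.cov(fb, rowvar=False))
    d = cov_a.shape[0]
    for cov in (cov_a, cov_b):
        # shrink only when near-singular, so well-posed cases stay exact
        if np.linalg.eigvalsh(cov).min() < 1e-10 * max(np.trace(cov) / d, 1e-300):
            cov += np.eye(d) * (1e-6 * np.trace(cov) / d + 1e-12)
    covmean = linalg.sqrtm(cov_a @ cov_b)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    diff = mu_a - mu_b
    val = float(diff @ diff + np.trace(cov_a + cov_b - 2.0 * covmean))
    return max(val, 0.0)


def score_assessment(records: pd.DataFrame) -> pd.DataFrame:
    """Score blinded real-vs-generated verdicts, per rater and pooled.

    ``records`` columns: image_id, true_source, rater_id, verdict, with
    true_source/verdict in {"real", "generated"}.  Returns one row per rater
    plus a "pooled" row with real-image accuracy, generated-image accuracy
    and the fraction of generated images judged real (1 - generated accuracy).
    """
    rec = pd.DataFrame(records)
    if rec.empty:
        raise ValueError("empty assessment table")
    for col in ("true_source", "verdict"):
        bad = set(rec[col].unique()) - {"real", "generated"}
        if bad:
            raise ValueError(f"unknown {col} values: {sorted(bad)}")

    def _score(df: pd.DataFrame) -> dict:
        real = df[df.true_source == "real"]
        gen = df[df.true_source == "generated"]
        acc_real = float((real.verdict == "real").mean()) if len(real) else np.nan
        acc_gen = float((gen.verdict == "generated").mean()) if len(gen) else np.nan
        return {
            "n_real": len(real),
            "n_generated": len(gen),
            "real_accuracy": acc_real,
            "generated_accuracy": acc_gen,
            "generated_judged_real": 1.0 - acc_gen if len(gen) else np.nan,
        }

    rows = []
    for rater, df in rec.groupby("rater_id", sort=True):
        rows.append({"rater_id": rater, **_score(df)})
    rows.append({"rater_id": "pooled", **_score(rec)})
    return pd.DataFrame(rows)


def summarize_scores(
    labels: pd.DataFrame, groups: tuple[Sequence[str], Sequence[str]]
) -> pd.DataFrame:
    """Per-group mean and SEM of consensus erythema and scale scores.

    Consensus per image is the mean over raters; SEM uses the sample
    standard deviation (ddof=1) over per-image consensus values divided by
    sqrt(n).  ``groups`` is (severe_ids, moderate_ids).
    """
    lab = pd.DataFrame(labels)
    per_image = lab.groupby("image_id")[["erythema", "scale"]].mean()
    rows = []
    for name, ids in zip(("severe", "moderate"), groups):
        ids = list(ids)
        if not ids:
            raise ValueError(f"empty group {name!r}")
        missing = set(ids) - set(per_image.index)
        if missing:
            raise ValueError(f"images with no labels: {sorted(missing)[:5]}")
        sub = per_image.loc[ids]
        n = len(sub)
        row = {"group": name, "n": n}
        for comp in ("erythema", "scale"):
            vals = sub[comp].to_numpy()
            row[f"{comp}_mean"] = float(vals.mean())
            row[f"{comp}_sem"] = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RealismReport:
    """The four comparison statistics for a pair of image sets."""

    histograms_a: np.ndarray
    histograms_b: np.ndarray
    spectrum_freq: np.ndarray
    spectrum_a: np.ndarray
    spectrum_b: np.ndarray
    sat_lum_a: np.ndarray
    sat_lum_b: np.ndarray
    frechet_distance: float
    meta: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "frechet_distance": self.frechet_distance,
            "n_a": int(self.histograms_a[0].sum()),
            "n_b": int(self.histograms_b[0].sum()),
            **self.meta,
        }


def realism_report(
    set_a: Sequence[np.ndarray],
    set_b: Sequence[np.ndarray],
    extractor: Callable[[Sequence[np.ndarray]], np.ndarray] = default_features,
) -> RealismReport:
    """Compute all four statistics for two image sets."""
    freq, spec_a = radial_power_spectrum(set_a)
    _, spec_b = radial_power_spectrum(set_b)
    return RealismReport(
        histograms_a=rgb_histograms(set_a),
        histograms_b=rgb_histograms(set_b),
        spectrum_freq=freq,
        spectrum_a=spec_a,
        spectrum_b=spec_b,
        sat_lum_a=saturation_luminance(set_a),
        sat_lum_b=saturation_luminance(set_b),
        frechet_distance=frechet_feature_distance(set_a, set_b, extractor),
        meta={"n_images_a": len(set_a), "n_images_b": len(set_b)},
    )
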