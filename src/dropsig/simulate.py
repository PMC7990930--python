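"""Monte-Carlo simulation of the droplet RT-PCR assay.

The generator emulates one experiment end to end: droplets receive a
Poisson(lambda) number of cells (uncapped — unlike the inverse model,
which stops at doublets; the gap is precisely what the simulation is
for), cell types are drawn i.i.d. from the composition ``c``, each
cell's signature is drawn from its type's reference profile ``r_k``,
one ambient-RNA signature per droplet is drawn from the mixture ambient
profile ``m = sum_k c_k n_k``, and the droplet displays the marker-wise
OR of everything it contains.  Running the experiment many times with
independent seeded streams yields the sampling distribution of the
composition estimate, with and without the ambient/doublet correction
step.

A fluorescence-level generator (:func:`synthesize_fluorescence`) maps
simulated signature tables to plausible droplet measurement tables
(area + per-channel intensities) so that the Step-1 classifier can be
exercised without instrument data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifiedTable  # noqa: F401  (re-exported convenience)
from .deconvolve import deconvolve_pipeline
from .signatures import MarkerPanel, SignatureProfile, DEFAULT_PANEL

__all__ = [
    "SimulationConfig",
    "FluorescenceModel",
    "ambient_mixture",
    "simulate_experiment",
    "simulate_dilution_series",
    "count_profiles",
    "simulate_trials",
    "synthesize_fluorescence",
    "default_reference_profiles",
    "default_ambient_profiles",
]


def default_reference_profiles(n_markers: int = 3) -> list[SignatureProfile]:
    """Synthetic stand-in reference profiles for three cell types.

    These are not measured profiles of any real cell line: they are
    synthetic defaults shaped like endpoint RT-PCR signature profiles of
    three distinguishable populations.  Type A is dominated by the
    marker-3-only signature, type B by marker 2, type C by marker 1;
    each carries all-negative dropout mass, a little cross-signature
    mass on the other single-marker signatures, and a little mass on
    doubles involving its own marker.  Fully overridable.
    """
    if n_markers != 3:
        raise ValueError("default profiles are defined for the 3-marker panel")
    g = 8

    def make(dominant_bit: int) -> SignatureProfile:
        vals = np.zeros(g)
        own = 1 << dominant_bit          # single-marker mask
        vals[own] = 0.85                 # own signature (index own+1)
        vals[0] = 0.09                   # all-negative dropout
        others = [b for b in range(3) if b != dominant_bit]
        for b in others:
            vals[1 << b] = 0.02          # cross-signature mass
            vals[own | (1 << b)] = 0.01  # own-marker doubles
        return SignatureProfile(vals, role="reference")

    # type A: marker 3 (bit 2); type B: marker 2 (bit 1); type C: marker 1 (bit 0)
    return [make(2), make(1), make(0)]


def default_ambient_profiles(n_markers: int = 3) -> list[SignatureProfile]:
    """Synthetic per-type ambient profiles paired with the default references.

    Each type's cell-free RNA mostly produces no signal (all-negative),
    with modest mass on its own marker and a trace on the others.
    """
    if n_markers != 3:
        raise ValueError("default profiles are defined for the 3-marker panel")
    g = 8

    def make(dominant_bit: int) -> SignatureProfile:
        vals = np.zeros(g)
        vals[0] = 0.85
        vals[1 << dominant_bit] = 0.12
        for b in range(3):
            if b != dominant_bit:
                vals[1 << b] = 0.015
        return SignatureProfile(vals, role="ambient")

    return [make(2), make(1), make(0)]


def ambient_mixture(composition: Sequence[float],
                    ambient_profiles: Sequence[SignatureProfile]) -> SignatureProfile:
    """Sample-level ambient profile m = sum_k c_k n_k (convex combination)."""
    c = np.asarray(composition, dtype=float)
    if c.ndim != 1 or len(ambient_profiles) != c.size:
        raise ValueError("composition and ambient profiles must have equal length")
    if np.any(c < 0) or abs(c.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be a probability vector")
    mats = np.stack([np.asarray(p, dtype=float) for p in ambient_profiles])
    if mats.ndim != 2:
        raise ValueError("ambient profiles must share one panel")
    return SignatureProfile(c @ mats, role="ambient-mixture")


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario definition for one simulated experiment series.

    Defaults follow the rare-cell study conditions: 200,000 droplets per
    trial at lambda = 0.2 with a (90%, 9.9%, 0.1%) three-population mix
    and the synthetic default profiles.
    """

    n_droplets: int = 200_000
    lambda_: float = 0.2
    composition: tuple[float, ...] = (0.90, 0.099, 0.001)
    references: tuple[SignatureProfile, ...] = field(
        default_factory=lambda: tuple(default_reference_profiles()))
    ambient_profiles: tuple[SignatureProfile, ...] = field(
        default_factory=lambda: tuple(default_ambient_profiles()))
    trials: int = 100
    seed: int = 0
    variant: str = "verbatim"

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.lambda_ < 0:
            raise ValueError("lambda must be >= 0")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        c = np.asarray(self.composition, dtype=float)
        if np.any(c < 0) or abs(c.sum() - 1.0) > 1e-9:
            raise ValueError("composition must be a probability vector")
        if len(self.references) != c.size or len(self.ambient_profiles) != c.size:
            raise ValueError("profiles must match the number of populations")
        object.__setattr__(self, "composition", tuple(float(x) for x in c))
        object.__setattr__(self, "references", tuple(self.references))
        object.__setattr__(self, "ambient_profiles", tuple(self.ambient_profiles))

    @property
    def n_markers(self) -> int:
        return self.references[0].n_markers

    @property
    def ambient_mixture(self) -> SignatureProfile:
        return ambient_mixture(self.composition, self.ambient_profiles)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def _trial_rng(base_seed: int, trial: int) -> np.random.Generator:
    """Independent, order-insensitive stream for one trial."""
    return np.random.default_rng(np.random.SeedSequence((base_seed, trial)))


def simulate_experiment(config: SimulationConfig, seed: int | None = None,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate one experiment's droplet signature table.

    Returns one row per droplet with the observed signature index plus
    the ground truth the generator knows: the cell count, the OR of the
    cell signatures alone, and the ambient draw.  Reproducible given the
    seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    d_count = config.n_droplets
    g = 1 << config.n_markers
    c = np.asarray(config.composition)

    cells_per_droplet = (rng.poisson(config.lambda_, size=d_count)
                         if config.lambda_ > 0 else np.zeros(d_count, dtype=np.int64))
    total_cells = int(cells_per_droplet.sum())

    # draw every cell at once, then OR within droplets via reduceat
    cell_mask = np.zeros(d_count, dtype=np.int64)
    if total_cells:
        types = rng.choice(c.size, size=total_cells, p=c)
        ref_mat = np.stack([np.asarray(r) for r in config.references])
        sig_masks = np.empty(total_cells, dtype=np.int64)
        for k in range(c.size):
            sel = types == k
            if sel.any():
                sig_masks[sel] = rng.choice(g, size=int(sel.sum()), p=ref_mat[k])
        occupied = cells_per_droplet > 0
        starts = np.concatenate([[0], np.cumsum(cells_per_droplet)[:-1]])
        cell_mask[occupied] = np.bitwise_or.reduceat(sig_masks, starts[occupied])

    m = np.asarray(config.ambient_mixture)
    ambient_mask = rng.choice(g, size=d_count, p=m)
    observed = cell_mask | ambient_mask

    return pd.DataFrame({
        "n_cells": cells_per_droplet,
        "cell_signature_index": cell_mask + 1,
        "ambient_signature_index": ambient_mask + 1,
        "signature_index": observed + 1,
    })


def count_profiles(table: pd.DataFrame, n_markers: int) -> tuple[SignatureProfile, SignatureProfile, float]:
    """Step-1-equivalent counting on a simulated signature table.

    Simulated signatures are already discrete, so classification reduces
    to counting: d over droplets with cells, n over empty droplets, and
    lambda from the empty fraction.
    """
    g = 1 << n_markers
    has_cell = table["n_cells"].to_numpy() > 0
    sig = table["signature_index"].to_numpy() - 1
    n_empty = int((~has_cell).sum())
    if n_empty == 0 or has_cell.all() or not has_cell.any():
        raise ValueError("need both empty and occupied droplets to form d, n, lambda")
    d = SignatureProfile.from_counts(np.bincount(sig[has_cell], minlength=g), role="droplet")
    n = SignatureProfile.from_counts(np.bincount(sig[~has_cell], minlength=g), role="ambient")
    lam = -np.log(n_empty / len(table))
    return d, n, float(lam)


def simulate_trials(config: SimulationConfig, progress: bool = False) -> dict:
    """Run the full pipeline over many seeded trials and summarize.

    Each trial simulates an experiment, counts d/n/lambda, runs the
    Step-2 inversion and the NNLS composition fit — both with and
    without Step 2 — and records the per-trial estimates.  The summary
    reports, per population, the mean estimate and the 95% confidence
    interval of that mean (t-based over trials), plus the 2.5/97.5
    percentile band of the trial distribution.
    """
    rows = []
    failures = 0
    iterator = range(config.trials)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm
        iterator = tqdm(iterator)
    for t in iterator:
        rng = _trial_rng(config.seed, t)
        table = simulate_experiment(config, rng=rng)
        try:
            d, n, lam = count_profiles(table, config.n_markers)
            corrected = deconvolve_pipeline((np.asarray(d), n, lam),
                                            config.references,
                                            variant=config.variant, step2=True)
            uncorrected = deconvolve_pipeline((np.asarray(d), n, lam),
                                              config.references,
                                              variant=config.variant, step2=False)
        except Exception:  # solver failure is recorded, not fatal
            failures += 1
            continue
        row = {"trial": t, "lambda_hat": lam}
        for k, w in enumerate(corrected["mixture"].weights):
            row[f"w{k}"] = float(w)
        for k, w in enumerate(uncorrected["mixture"].weights):
            row[f"w{k}_nostep2"] = float(w)
        rows.append(row)

    estimates = pd.DataFrame(rows)
    k_pop = len(config.composition)
    summary: dict = {"trials": config.trials, "failures": failures,
                     "composition": list(config.composition),
                     "lambda": config.lambda_, "n_droplets": config.n_droplets,
                     "populations": {}}
    n_ok = len(estimates)
    for k in range(k_pop):
        for tag, col in (("step2", f"w{k}"), ("nostep2", f"w{k}_nostep2")):
            x = estimates[col].to_numpy()
            mean = float(x.mean())
            sd = float(x.std(ddof=1)) if n_ok > 1 else 0.0
            half = float(stats.t.ppf(0.975, n_ok - 1) * sd / np.sqrt(n_ok)) if n_ok > 1 else 0.0
            summary["populations"].setdefault(k, {})[tag] = {
                "mean": mean,
                "sd": sd,
                "ci_low": mean - half,
                "ci_high": mean + half,
                "pct_2.5": float(np.percentile(x, 2.5)),
                "pct_97.5": float(np.percentile(x, 97.5)),
            }
    return {"estimates": estimates, "summary": summary}


def simulate_dilution_series(
    concentrations: Sequence[float],
    n_droplets: int = 100_000,
    volume_nl: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Limiting-dilution experiment on in-vitro transcripts.

    For each true concentration (copies/nL), transcript copies per
    droplet are Poisson with mean concentration * volume; a droplet is
    positive when it holds at least one copy.  The concentration is then
    estimated back from the negative fraction.  Returns one row per
    dilution with the true and estimated concentration; estimated
    dilution factors regress on the true ones with slope ~= 1 when the
    assay is in its quantifiable range.
    """
    from .occupancy import concentration_from_negatives

    rng = np.random.default_rng(seed)
    rows = []
    for conc in concentrations:
        lam = conc * volume_nl
        positives = rng.poisson(lam, size=n_droplets) > 0
        frac_neg = 1.0 - positives.mean()
        est = (concentration_from_negatives(frac_neg, volume_nl)
               if 0.0 < frac_neg < 1.0 else np.nan)
        rows.append({"true_copies_per_nl": conc,
                     "fraction_negative": frac_neg,
                     "estimated_copies_per_nl": est})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FluorescenceModel:
    """Intensity/area emission model mapping signatures to measurements.

    Synthetic by construction: channel intensities are log-normal with a
    well-separated negative and positive mode (defaults two decades
    apart, ~13 sigma in log10 space), the cell-dye signal scales with
    cell count plus a background level, and droplet area is Gaussian
    with an inflation factor for multi-cell droplets (coalescence-like).
    """

    negative_log10: float = 2.0
    positive_log10: float = 4.0
    sigma_log10: float = 0.15
    dye_negative_log10: float = 2.0
    dye_positive_log10: float = 4.0
    dye_background_log10: float = 0.0   # added to the dye negative mode
    area_mean: float = 12000.0
    area_sd: float = 600.0
    doublet_area_factor: float = 1.12   # per extra cell

    def __post_init__(self) -> None:
        if self.positive_log10 <= self.negative_log10:
            raise ValueError("positive mode must exceed the negative mode")
        if self.sigma_log10 <= 0 or self.area_sd <= 0:
            raise ValueError("scales must be positive")


def synthesize_fluorescence(table: pd.DataFrame, panel: MarkerPanel = DEFAULT_PANEL,
                            model: FluorescenceModel | None = None,
                            seed: int = 0) -> pd.DataFrame:
    """Render a simulated signature table as a droplet measurement table.

    Output columns follow the CellProfiler-style defaults consumed by
    :mod:`dropsig.io` (``AreaShape_Area`` plus one
    ``Intensity_MeanIntensity_<channel>`` per channel), so the result
    round-trips through the Step-1 classifier.
    """
    model = model or FluorescenceModel()
    rng = np.random.default_rng(seed)
    n = len(table)
    n_cells = table["n_cells"].to_numpy()
    sig_mask = table["signature_index"].to_numpy() - 1

    area = rng.normal(model.area_mean, model.area_sd, size=n)
    area *= model.doublet_area_factor ** np.maximum(n_cells - 1, 0)
    out = {"AreaShape_Area": np.maximum(area, 1.0)}

    dye_neg = model.dye_negative_log10 + model.dye_background_log10
    dye_mu = np.where(n_cells > 0,
                      model.dye_positive_log10 + np.log10(np.maximum(n_cells, 1)),
                      dye_neg)
    out[f"Intensity_MeanIntensity_{panel.cell_channel}"] = 10.0 ** rng.normal(
        dye_mu, model.sigma_log10)

    for bit, ch in enumerate(panel.marker_channels()):
        positive = (sig_mask >> bit & 1).astype(bool)
        mu = np.where(positive, model.positive_log10, model.negative_log10)
        out[f"Intensity_MeanIntensity_{ch}"] = 10.0 ** rng.normal(mu, model.sigma_log10)

    return pd.DataFrame(out)
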