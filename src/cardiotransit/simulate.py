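"""Synthetic line-scan recordings and negative-binomial count data.

The imaging generator produces paced Rhod-2-like fluorescence line-scans
with per-pixel Poisson photon noise and a hierarchical cell population
(between-differentiation-batch shifts plus between-cell variation).  The
waveform is built so that the analyzer definitions (15%-height onset, peak,
half-decay) recover the generating parameters exactly on noiseless input:

* resting baseline F0 for the first fifth of each pacing epoch,
* a raised-cosine upstroke scaled so the 15%-threshold-to-peak interval
  equals ``rise_time_ms``,
* an asymptotically exponential decay crossing half height exactly at
  ``decay50_ms``, with a rounded shoulder at the peak whose curvature
  matches the upstroke's so the waveform is C1 and locally symmetric
  there (a linear smoother then leaves the peak location unbiased).

The count generator draws gene x sample matrices with NB(mu, alpha) noise
(Var = mu + alpha mu^2), multiplicative library-size factors, and planted
per-stage log2 fold changes carried as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import asdict
from typing import Iterator, Mapping

import numba
import numpy as np
import pandas as pd

from .params import (
    HUMAN_STAGES,
    MOUSE_STAGES,
    AcquisitionParams,
    ConcordancePreset,
    CountSimParams,
    PopulationPreset,
    TransientParams,
    METRIC_NAMES,
)
from .trace import LineScanRecording

__all__ = [
    "gen_transient_waveform",
    "gen_linescan",
    "draw_population_params",
    "gen_cell_population",
    "gen_counts",
    "gen_de_tables",
    "build_concordance_params",
]

# fraction of each pacing epoch spent at rest before the stimulus; gives the
# baseline estimator an unambiguous resting segment (~20% duty)
ONSET_FRACTION = 0.2

# raised-cosine fraction of the upstroke that precedes the 15%-height
# crossing: solve 0.5*(1 - cos(pi*x)) = 0.15  ->  x = acos(0.7)/pi
_PRE_ONSET_FRAC = math.acos(0.7) / math.pi


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Waveform

def gen_transient_waveform(
    params: TransientParams,
    dt: float,
    duration: float,
    onset_fraction: float = ONSET_FRACTION,
) -> np.ndarray:
    """Noiseless fluorescence waveform sampled at ``dt`` for ``duration`` s.

    Values are in the photon-unit F scale of ``params.baseline_f0``.  One
    transient is emitted per pacing epoch, delayed by
    ``onset_fraction / pacing_hz`` from the epoch start.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    epoch = params.epoch_s
    if duration < epoch:
        raise ValueError("duration must cover at least one pacing epoch")
    if not (0.0 <= onset_fraction < 1.0):
        raise ValueError("onset_fraction must be in [0, 1)")

    n = int(round(duration / dt))
    t = np.arange(n) * dt
    f0 = params.baseline_f0
    height = f0 * (params.amplitude_peak - 1.0)
    if height == 0.0:
        return np.full(n, f0)

    onset = onset_fraction * epoch
    t_rise_total = (params.rise_time_ms / 1000.0) / (1.0 - _PRE_ONSET_FRAC)
    d50 = params.decay50_ms / 1000.0
    if onset + t_rise_total + d50 >= epoch:
        raise ValueError(
            "transient (onset delay + upstroke + half-decay) does not fit the "
            f"pacing epoch of {epoch:.3f} s"
        )

    # decay time-warp phi(t) = k*(sqrt(t^2 + b^2) - b): zero slope at the
    # peak, phi(d50) = d50 so the half-height crossing is exact, and
    # asymptotically linear (exponential tail).  b matches the decay-side
    # curvature k*ln2/(d50*b) to the upstroke's pi^2/(2*T_r^2).
    b = 2.0 * math.log(2.0) * t_rise_total**2 / (math.pi**2 * d50)
    b = min(max(b, dt), d50)
    for _ in range(3):  # fixed point in k
        k = d50 / (math.sqrt(d50**2 + b**2) - b)
        b_new = min(max(2.0 * math.log(2.0) * k * t_rise_total**2 / (math.pi**2 * d50), dt), d50)
        if abs(b_new - b) < 1e-12:
            break
        b = b_new
    k = d50 / (math.sqrt(d50**2 + b**2) - b)

    phase = t % epoch
    wave = np.full(n, f0)
    rising = (phase >= onset) & (phase < onset + t_rise_total)
    wave[rising] = f0 + height * 0.5 * (
        1.0 - np.cos(np.pi * (phase[rising] - onset) / t_rise_total)
    )
    falling = phase >= onset + t_rise_total
    td = phase[falling] - onset - t_rise_total
    phi = k * (np.sqrt(td**2 + b**2) - b)
    wave[falling] = f0 + height * np.exp2(-phi / d50)
    return wave


# ---------------------------------------------------------------------------
# Exact Poisson sampling, fast path for per-line-constant rates.
#
# Within a line the expected photon count is constant (flat spatial profile),
# so each line can be sampled by inverting a tabulated pmf.  The table spans
# lambda +/- 10*sqrt(lambda) (+20), leaving truncated mass < 1e-20; sampling
# uses Vose's alias method with a single uniform per draw.

@numba.njit(cache=True)
def _poisson_rows_alias(lam_rows: np.ndarray, U: np.ndarray, out: np.ndarray) -> None:  # pragma: no cover - numba
    n_rows, n_pixels = U.shape
    maxn = 4096
    pmf = np.empty(maxn, dtype=np.float64)
    prob = np.empty(maxn, dtype=np.float64)
    alias = np.empty(maxn, dtype=np.int64)
    small = np.empty(maxn, dtype=np.int64)
    large = np.empty(maxn, dtype=np.int64)
    for i in range(n_rows):
        lam = lam_rows[i]
        if lam <= 0.0:
            for j in range(n_pixels):
                out[i, j] = 0.0
            continue
        sd = math.sqrt(lam)
        lo = int(max(0.0, math.floor(lam - 10.0 * sd)))
        n = int(math.ceil(lam + 10.0 * sd) + 20) - lo + 1
        logp = lo * math.log(lam) - lam - math.lgamma(lo + 1.0)
        p = math.exp(logp)
        tot = p
        pmf[0] = p
        for k in range(1, n):
            p = p * lam / (lo + k)
            pmf[k] = p
            tot += p
        ns = 0
        nl = 0
        scale = n / tot
        for k in range(n):
            pk = pmf[k] * scale
            pmf[k] = pk
            if pk < 1.0:
                small[ns] = k
                ns += 1
            else:
                large[nl] = k
                nl += 1
        while ns > 0 and nl > 0:
            ns -= 1
            s = small[ns]
            l = large[nl - 1]
            prob[s] = pmf[s]
            alias[s] = l
            pmf[l] = pmf[l] - (1.0 - pmf[s])
            if pmf[l] < 1.0:
                nl -= 1
                small[ns] = l
                ns += 1
        while nl > 0:
            nl -= 1
            prob[large[nl]] = 1.0
            alias[large[nl]] = large[nl]
        while ns > 0:
            ns -= 1
            prob[small[ns]] = 1.0
            alias[small[ns]] = small[ns]
        for j in range(n_pixels):
            x = U[i, j] * n
            idx = int(x)
            if idx >= n:
                idx = n - 1
            frac = x - idx
            if frac < prob[idx]:
                out[i, j] = lo + idx
            else:
                out[i, j] = lo + alias[idx]


def poisson_rows(lam_rows: np.ndarray, n_pixels: int, rng: np.random.Generator) -> np.ndarray:
    """Sample an (n_rows, n_pixels) Poisson image with per-row constant rate."""
    lam_rows = np.ascontiguousarray(lam_rows, dtype=np.float64)
    out = np.empty((lam_rows.size, n_pixels), dtype=np.float64)
    U = rng.random((lam_rows.size, n_pixels))
    _poisson_rows_alias(lam_rows, U, out)
    return out


# ---------------------------------------------------------------------------
# Line-scan generation

def _spatial_profile(acq: AcquisitionParams, kind: str) -> np.ndarray:
    if kind == "flat":
        return np.ones(acq.n_pixels)
    if kind == "gaussian":
        # cell brighter in the middle of the scan; unit mean so the spatial
        # average still equals the waveform
        x = np.linspace(-1.0, 1.0, acq.n_pixels)
        prof = np.exp(-0.5 * (x / 0.5) ** 2)
        return prof / prof.mean()
    raise ValueError(f"unknown spatial profile: {kind!r}")


def gen_linescan(
    cell: TransientParams,
    acq: AcquisitionParams,
    seed: int | np.random.Generator | None = None,
    noise: bool = True,
    spatial_profile: str = "flat",
) -> LineScanRecording:
    """Simulate one line-scan recording of a paced cell.

    Per-pixel intensities are Poisson with expectation
    ``photon_gain * waveform(t) * profile(x) * exp(-bleach_rate * t)``.
    With ``noise=False`` the expectation itself is returned (infinite-photon
    limit).  Ground truth is attached under ``metadata['ground_truth']``.
    """
    rng = _as_rng(seed)
    wave = gen_transient_waveform(cell, acq.dt, acq.duration_s)
    t = np.arange(acq.n_lines) * acq.dt
    decay = np.exp(-acq.bleach_rate * t) if acq.bleach_rate else 1.0
    rate_rows = acq.photon_gain * wave * decay
    profile = _spatial_profile(acq, spatial_profile)

    if not noise:
        intensity = rate_rows[:, None] * profile[None, :]
    elif spatial_profile == "flat":
        intensity = poisson_rows(rate_rows, acq.n_pixels, rng)
    else:
        intensity = rng.poisson(rate_rows[:, None] * profile[None, :]).astype(float)

    meta = {
        "ground_truth": asdict(cell),
        "noise": noise,
        "spatial_profile": spatial_profile,
        "acquisition": asdict(acq),
    }
    return LineScanRecording(
        intensity=intensity,
        line_rate_hz=acq.line_rate_hz,
        pixel_size_um=acq.pixel_size_um,
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# Hierarchical cell population

def batch_sizes(n_cells: int, n_batches: int) -> list[int]:
    """Near-even split of cells over differentiation batches (181/3 -> 61,60,60)."""
    base, rem = divmod(n_cells, n_batches)
    return [base + 1 if b < rem else base for b in range(n_batches)]


def _draw_metric(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lower: float,
    metric: str,
    max_retries: int = 100,
) -> float:
    for _ in range(max_retries):
        v = rng.normal(mean, sd) if sd > 0 else mean
        if v > lower:
            return float(v)
    raise RuntimeError(
        f"could not draw a valid value for metric {metric!r} after "
        f"{max_retries} retries (mean {mean:.4g}, sd {sd:.4g})"
    )


def draw_population_params(
    preset: PopulationPreset,
    n_cells: int,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw ground-truth transient parameters for a hierarchical population.

    Batch effects are Normal(0, sd_between_diff) per metric; cell values are
    Normal(batch-shifted mean, cv * group mean), truncated to valid
    parameters (bounded retries).  Returns one row per cell with columns
    ``cell_id, batch`` and the three metrics.
    """
    if n_cells < preset.n_diff:
        raise ValueError("n_cells must be >= n_diff")
    rng = _as_rng(seed)
    means = {m: preset.metric_mean(m) for m in METRIC_NAMES}
    lower = {"amplitude_peak": 1.0, "rise_time_ms": 0.0, "decay50_ms": 0.0}
    epoch_ms = 1000.0 / preset.mean_params.pacing_hz

    shifts = {
        b: {m: rng.normal(0.0, preset.sd_between_diff[m]) for m in METRIC_NAMES}
        for b in range(preset.n_diff)
    }
    rows = []
    cell = 0
    for b, size in enumerate(batch_sizes(n_cells, preset.n_diff)):
        for _ in range(size):
            drawn = {}
            for m in METRIC_NAMES:
                drawn[m] = _draw_metric(
                    rng,
                    means[m] + shifts[b][m],
                    preset.cv_between_cell[m] * means[m],
                    lower[m],
                    m,
                )
            # the epoch-fit constraint binds through the decay tail
            retries = 0
            while drawn["rise_time_ms"] + 2.0 * drawn["decay50_ms"] >= epoch_ms:
                retries += 1
                if retries > 100:
                    raise RuntimeError(
                        "could not satisfy the epoch-fit constraint for metric "
                        "'decay50_ms' after 100 retries"
                    )
                drawn["decay50_ms"] = _draw_metric(
                    rng,
                    means["decay50_ms"] + shifts[b]["decay50_ms"],
                    preset.cv_between_cell["decay50_ms"] * means["decay50_ms"],
                    lower["decay50_ms"],
                    "decay50_ms",
                )
            rows.append(
                {
                    "cell_id": f"{preset.group_label}_c{cell:03d}",
                    "group": preset.group_label,
                    "batch": b,
                    **drawn,
                }
            )
            cell += 1
    return pd.DataFrame(rows)


def gen_cell_population(
    preset: PopulationPreset,
    n_cells: int,
    acq: AcquisitionParams,
    seed: int | None = None,
    noise: bool = True,
) -> Iterator[LineScanRecording]:
    """Stream line-scan recordings for a hierarchical cell population.

    Recordings are yielded one at a time (a full-scale population does not
    fit in memory); batch labels and ground truth ride in ``metadata``.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_cells + 1)
    cells = draw_population_params(preset, n_cells, np.random.default_rng(children[0]))
    base = preset.mean_params
    for i, row in cells.iterrows():
        params = TransientParams(
            amplitude_peak=row["amplitude_peak"],
            rise_time_ms=row["rise_time_ms"],
            decay50_ms=row["decay50_ms"],
            baseline_f0=base.baseline_f0,
            pacing_hz=base.pacing_hz,
        )
        rec = gen_linescan(
            params, acq, np.random.default_rng(children[i + 1]), noise=noise
        )
        rec.metadata["cell_id"] = row["cell_id"]
        rec.metadata["batch"] = int(row["batch"])
        rec.metadata["group"] = preset.group_label
        yield rec


# ---------------------------------------------------------------------------
# Negative-binomial counts

def gen_counts(params: CountSimParams, seed: int | np.random.Generator | None = None):
    """Simulate a gene x sample NB count matrix with planted effects.

    counts[g, s] ~ NB(mean = sf_s * mu_g * 2**lfc[g, stage(s)],
    Var = mu + dispersion * mu^2); ground truth is attached on the returned
    :class:`~cardiotransit.de.CountMatrix` as ``truth``.
    """
    from .de import CountMatrix  # deferred to avoid an import cycle

    rng = _as_rng(seed)
    samples = list(params.design)
    stages = list(params.stages)
    G, S = params.n_genes, len(samples)

    if params.base_mean is not None:
        mu0 = np.full(G, float(params.base_mean))
    else:
        mu0 = rng.lognormal(
            mean=math.log(params.base_mean_median),
            sigma=params.base_mean_log_sigma,
            size=G,
        )
    for g, v in params.base_mean_overrides.items():
        mu0[g] = v

    lfc = np.zeros((G, len(stages)))
    for g, effects in params.planted_effects.items():
        for stage, val in effects.items():
            lfc[g, stages.index(stage)] = val

    lo, hi = params.size_factor_range
    sf = rng.uniform(lo, hi, size=S)
    stage_idx = np.array([stages.index(params.design[s]) for s in samples])
    mu = sf[None, :] * mu0[:, None] * np.exp2(lfc[:, stage_idx])

    alpha = np.broadcast_to(np.asarray(params.dispersion, dtype=float), (G,))
    if np.all(alpha == 0):
        counts = rng.poisson(mu)
    else:
        a = np.where(alpha > 0, alpha, 1.0)[:, None]
        r = 1.0 / a
        p = r / (r + mu)
        nb = rng.negative_binomial(r, p)
        pois = rng.poisson(mu)
        counts = np.where(alpha[:, None] > 0, nb, pois)

    gene_ids = [f"{params.gene_prefix}{g:05d}" for g in range(G)]
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    truth = pd.DataFrame(
        {"base_mean": mu0, "dispersion": alpha},
        index=gene_ids,
    )
    for j, stage in enumerate(stages):
        truth[f"lfc_{stage}"] = lfc[:, j]
    truth["planted"] = [g in params.planted_effects for g in range(G)]
    cm = CountMatrix(counts_df, dict(params.design))
    cm.truth = truth
    return cm


# ---------------------------------------------------------------------------
# Paired human/mouse concordance fixture

def _species_design(prefix: str, stages: tuple[str, ...], ns: tuple[int, ...]) -> dict[str, str]:
    design: dict[str, str] = {}
    for stage, n in zip(stages, ns):
        for i in range(n):
            design[f"{prefix}_{stage}_{i + 1}"] = stage
    return design


def build_concordance_params(
    preset: ConcordancePreset, rng: np.random.Generator
) -> tuple[CountSimParams, CountSimParams, pd.DataFrame]:
    """Draw the planted-effect configuration for both species.

    Returns human and mouse :class:`CountSimParams` plus a per-gene truth
    table of the planted effects (indexed by gene number).
    """
    n_planted = preset.n_planted
    human_fx: dict[int, dict[str, float]] = {}
    mouse_fx: dict[int, dict[str, float]] = {}
    records = []
    for g in range(n_planted):
        if g == 0:
            h_early, h_late = preset.crispld1_human
            m_early, m_late = preset.crispld1_mouse
        else:
            sign = 1.0 if g % 2 == 0 else -1.0
            mag_early = rng.uniform(*preset.planted_early_lfc)
            mag_late = mag_early + rng.uniform(*preset.planted_step_lfc)
            shrink = rng.uniform(0.0, 0.2)
            h_early, h_late = sign * mag_early, sign * mag_late
            m_early, m_late = sign * (mag_early - shrink), sign * (mag_late - shrink)
        human_fx[g] = {HUMAN_STAGES[1]: h_early, HUMAN_STAGES[2]: h_late}
        mouse_fx[g] = {MOUSE_STAGES[1]: m_early, MOUSE_STAGES[2]: m_late}
        records.append(
            {
                "gene": g,
                "human_lfc_ch": h_early,
                "human_lfc_hf": h_late,
                "mouse_lfc_ch": m_early,
                "mouse_lfc_hf": m_late,
            }
        )

    # planted genes get well-expressed baselines; background is lognormal
    planted_mu = dict(
        enumerate(rng.uniform(*preset.planted_base_mean, size=n_planted))
    )

    def species_params(prefix: str, stages, ns, fx) -> CountSimParams:
        return CountSimParams(
            n_genes=preset.n_genes,
            design=_species_design(prefix[0], stages, ns),
            stages=stages,
            dispersion=preset.dispersion,
            size_factor_range=preset.size_factor_range,
            planted_effects=fx,
            base_mean_overrides=planted_mu,
            gene_prefix=prefix,
        )

    human = species_params("HGENE", HUMAN_STAGES, preset.human_n, human_fx)
    mouse = species_params("MGENE", MOUSE_STAGES, preset.mouse_n, mouse_fx)
    truth = pd.DataFrame(records).set_index("gene") if records else pd.DataFrame()
    return human, mouse, truth


def gen_de_tables(
    preset: ConcordancePreset, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate both species and run the DE stages end to end.

    Returns ``(human_table, mouse_table, ortholog_map, truth)``. Each species
    table has one row per gene with ``log2fc_ch/q_ch`` (early stage vs
    control) and ``log2fc_hf/q_hf`` (late stage vs control).  The ortholog
    map is a 1:1 bijection between the simulated gene sets.
    """
    from .de import de_table, size_factors

    ss = np.random.SeedSequence(seed)
    fx_rng, h_rng, m_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    human_p, mouse_p, truth = build_concordance_params(preset, fx_rng)

    def run_species(params: CountSimParams, rng, stages) -> pd.DataFrame:
        cm = gen_counts(params, rng)
        sf = size_factors(cm.counts)
        early = de_table(cm, contrast=(stages[1], stages[0]), factors=sf)
        late = de_table(cm, contrast=(stages[2], stages[0]), factors=sf)
        out = pd.DataFrame(
            {
                "gene_id": early["gene_id"],
                "base_mean": early["base_mean"],
                "log2fc_ch": early["log2fc"].to_numpy(),
                "p_ch": early["p_value"].to_numpy(),
                "q_ch": early["q_value"].to_numpy(),
                "log2fc_hf": late["log2fc"].to_numpy(),
                "p_hf": late["p_value"].to_numpy(),
                "q_hf": late["q_value"].to_numpy(),
            }
        )
        out["planted"] = cm.truth["planted"].to_numpy()
        return out

    human = run_species(human_p, h_rng, HUMAN_STAGES)
    mouse = run_species(mouse_p, m_rng, MOUSE_STAGES)
    ortho = pd.DataFrame(
        {
            "human_id": human["gene_id"],
            "mouse_id": mouse["gene_id"],
            "mapping_type": "one2one",
        }
    )
    return human, mouse, ortho, truth
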