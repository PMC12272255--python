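"""Synthetic multi-participant cohort with planted structure.

The generator emulates the statistical features the analysis relies on, at
the study's dimensions (130 participants, 185 homotopic pairs, 240 rest
volumes at TR = 2 s), with ground truth for recovery tests:

* task contrasts: planted pairs carry a positive mean activation on both
  hemispheres plus an asymmetry split symmetrically across sides
  (+delta/2 on the favored side, -delta/2 on the other), in units of the
  unit-variance participant noise; unplanted pairs are pure noise;
* rest time series: each planted module has a latent signal; a region is
  its module latent times a loading plus independent noise, every component
  band-limited to 0.01-0.1 Hz by an ideal zero-phase frequency-domain mask.
  Module latents are correlated according to signed between-module targets,
  so inter-network coupling has a configurable sign pattern;
* connector hubs: listed regions additionally load on secondary module
  latents and carry reduced idiosyncratic noise, which elevates both their
  within-network degree and betweenness.

Between-module targets are specified on the region-correlation scale and
converted internally to latent correlations by undoing the attenuation
factor (loading^2 + noise_sd^2) / loading^2; a region-level target can
therefore never exceed the within-module correlation, which is a structural
property of any latent-factor model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .selection import ContrastTable

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "TimeSeriesPanel",
    "simulate_contrasts",
    "simulate_rest_timeseries",
    "planted_truth",
    "demo_config",
    "band_limited_noise",
]


@dataclass(frozen=True)
class CohortConfig:
    """Everything the generator needs, including the planted ground truth.

    ``planted_pairs`` maps a pair id to the favored hemisphere; the selected
    region of a planted pair shares the pair's id.  ``module_spec`` maps
    module name -> member region ids (a subset of the planted pair ids);
    the rest panel covers exactly those members.  ``between_module_r`` maps
    an unordered module pair to a signed region-level correlation target.
    ``hub_spec`` maps a connector-hub region to its secondary modules.
    """

    n_participants: int = 130
    n_pairs: int = 185
    pair_ids: tuple[str, ...] = ()
    planted_pairs: dict = field(default_factory=dict)
    activation_effect: float = 1.5
    asymmetry_effect: float = 1.0
    module_spec: dict = field(default_factory=dict)
    between_module_r: dict = field(default_factory=dict)
    hub_spec: dict = field(default_factory=dict)
    loading: float = 1.0
    noise_sd: float = 1.0
    hub_noise_scale: float = 0.45
    hub_cross_loading: float = 0.25
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    band: tuple[float, float] = (0.01, 0.1)
    excluded_pairs: tuple[str, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2 or self.n_pairs < 1:
            raise ValueError("need >= 2 participants and >= 1 pair")
        pair_ids = self.pair_ids or tuple(
            f"pair{i + 1:03d}" for i in range(self.n_pairs)
        )
        if len(pair_ids) != self.n_pairs or len(set(pair_ids)) != self.n_pairs:
            raise ValueError("pair_ids must be n_pairs unique labels")
        object.__setattr__(self, "pair_ids", pair_ids)
        unknown = set(self.planted_pairs) - set(pair_ids)
        if unknown:
            raise ValueError(f"planted pair ids outside the pair set: {sorted(unknown)}")
        bad = {h for h in self.planted_pairs.values() if h not in ("Left", "Right")}
        if bad:
            raise ValueError(f"planted hemisphere must be Left/Right, got {sorted(bad)}")
        if self.activation_effect < 0 or self.asymmetry_effect < 0:
            raise ValueError("effect sizes must be nonnegative")
        members_all: list[str] = []
        for module, members in self.module_spec.items():
            members = tuple(members)
            if self.between_module_r and len(members) < 2:
                raise ValueError(
                    f"module {module!r} has < 2 members but between-module "
                    "targets are set"
                )
            members_all.extend(members)
        if len(set(members_all)) != len(members_all):
            raise ValueError("module memberships must be disjoint")
        for (a, b), r in self.between_module_r.items():
            if a not in self.module_spec or b not in self.module_spec:
                raise ValueError(f"unknown module in between_module_r: {(a, b)}")
            if not abs(r) < 1:
                raise ValueError("between-module targets must satisfy |r| < 1")
        for region, secondary in self.hub_spec.items():
            if region not in set(members_all):
                raise ValueError(f"hub region {region!r} not in any module")
            for s in secondary:
                if s not in self.module_spec:
                    raise ValueError(f"unknown secondary module {s!r} for hub {region!r}")
        if self.n_timepoints < 8:
            raise ValueError("need >= 8 timepoints")
        if not 0 <= self.band[0] < self.band[1] <= 0.5 / self.tr_seconds:
            raise ValueError("band must lie within (0, Nyquist]")

    @property
    def region_ids(self) -> tuple[str, ...]:
        """Rest-panel regions: module members in module order."""
        out: list[str] = []
        for members in self.module_spec.values():
            out.extend(members)
        return tuple(out)

    def attenuation(self) -> float:
        return (self.loading**2 + self.noise_sd**2) / self.loading**2

    def latent_correlation(self) -> np.ndarray:
        """Module-latent correlation matrix implied by the region targets."""
        modules = list(self.module_spec)
        c = np.eye(len(modules))
        att = self.attenuation()
        for (a, b), r in self.between_module_r.items():
            i, j = modules.index(a), modules.index(b)
            rho = r * att
            if abs(rho) >= 1:
                raise ValueError(
                    f"target r={r} for {(a, b)} is unreachable: latent "
                    f"correlation {rho:.3f} out of range"
                )
            c[i, j] = c[j, i] = rho
        if np.linalg.eigvalsh(c).min() < 1e-9:
            raise ValueError("between_module_r targets give a non-PSD latent "
                             "correlation matrix")
        return c


@dataclass(frozen=True)
class GroundTruth:
    """The selection, module and hub truth implied by a CohortConfig."""

    selected_regions: frozenset  # of (pair_id, hemisphere)
    module_labels: dict  # region id -> module name
    hub_regions: frozenset


@dataclass(frozen=True)
class TimeSeriesPanel:
    """Per-participant region-by-time rest series."""

    data: np.ndarray  # (participants, regions, timepoints)
    region_ids: tuple[str, ...]
    participant_ids: tuple[str, ...]
    tr_seconds: float

    def to_dir(self, path: str | Path) -> None:
        """One TSV per participant (regions x timepoints) plus a manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for i, pid in enumerate(self.participant_ids):
            pd.DataFrame(self.data[i], index=list(self.region_ids)).to_csv(
                path / f"{pid}.tsv", sep="\t"
            )
        pd.DataFrame(
            {"participant": list(self.participant_ids), "tr_seconds": self.tr_seconds}
        ).to_csv(path / "manifest.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "TimeSeriesPanel":
        path = Path(path)
        manifest = pd.read_csv(path / "manifest.tsv", sep="\t", dtype={"participant": str})
        participants = tuple(manifest["participant"])
        mats, regions = [], None
        for pid in participants:
            df = pd.read_csv(path / f"{pid}.tsv", sep="\t", index_col=0,
                             float_precision="round_trip")
            regions = tuple(str(r) for r in df.index)
            mats.append(df.to_numpy(dtype=float))
        return cls(
            np.stack(mats), regions, participants,
            float(manifest["tr_seconds"].iloc[0]),
        )


def band_limited_noise(
    rng: np.random.Generator,
    n_series: int,
    n_timepoints: int,
    tr_seconds: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Unit-variance white Gaussian noise restricted to the passband.

    White noise is masked in the frequency domain (ideal zero-phase filter)
    and rescaled so the expected variance is one; all power lies strictly
    inside the band.
    """
    white = rng.standard_normal((n_series, n_timepoints))
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError("passband contains no DFT bin at this length and TR")
    # count kept full-spectrum bins: DC and Nyquist once, others twice
    mult = np.full(mask.shape, 2.0)
    mult[0] = 1.0
    if n_timepoints % 2 == 0:
        mult[-1] = 1.0
    kept = float((mask * mult).sum())
    spec = np.fft.rfft(white, axis=-1) * mask
    return np.fft.irfft(spec, n=n_timepoints, axis=-1) * np.sqrt(n_timepoints / kept)


def simulate_contrasts(cfg: CohortConfig) -> ContrastTable:
    """Task-contrast table with planted activation and asymmetry effects."""
    rng = np.random.default_rng([cfg.rng_seed, 0])
    values = rng.standard_normal((cfg.n_participants, cfg.n_pairs, 2))
    index = {p: i for i, p in enumerate(cfg.pair_ids)}
    for pair, hemisphere in cfg.planted_pairs.items():
        j = index[pair]
        favored = 0 if hemisphere == "Left" else 1
        values[:, j, :] += cfg.activation_effect
        values[:, j, favored] += cfg.asymmetry_effect / 2.0
        values[:, j, 1 - favored] -= cfg.asymmetry_effect / 2.0
    participants = tuple(f"sub{i + 1:03d}" for i in range(cfg.n_participants))
    table = ContrastTable(values, participants, cfg.pair_ids)
    if cfg.excluded_pairs:
        table = table.drop_pairs(cfg.excluded_pairs)
    return table


def simulate_rest_timeseries(cfg: CohortConfig) -> TimeSeriesPanel:
    """Band-limited rest series with modular covariance and connector hubs."""
    if not cfg.module_spec:
        raise ValueError("module_spec is empty: nothing to simulate")
    rng = np.random.default_rng([cfg.rng_seed, 1])
    modules = list(cfg.module_spec)
    chol = np.linalg.cholesky(cfg.latent_correlation())
    regions = cfg.region_ids
    module_of = {
        r: m for m, members in cfg.module_spec.items() for r in members
    }
    n_p, n_r, n_t = cfg.n_participants, len(regions), cfg.n_timepoints
    data = np.empty((n_p, n_r, n_t))
    for p in range(n_p):
        latents = chol @ band_limited_noise(
            rng, len(modules), n_t, cfg.tr_seconds, cfg.band
        )
        noise = band_limited_noise(rng, n_r, n_t, cfg.tr_seconds, cfg.band)
        for i, region in enumerate(regions):
            m = modules.index(module_of[region])
            x = cfg.loading * latents[m]
            sigma = cfg.noise_sd
            if region in cfg.hub_spec:
                sigma *= cfg.hub_noise_scale
                for sec in cfg.hub_spec[region]:
                    x = x + cfg.hub_cross_loading * latents[modules.index(sec)]
            data[p, i] = x + sigma * noise[i]
    participants = tuple(f"sub{i + 1:03d}" for i in range(n_p))
    return TimeSeriesPanel(data, regions, participants, cfg.tr_seconds)


def planted_truth(cfg: CohortConfig) -> GroundTruth:
    """The ground truth a perfect analysis would recover from this cohort."""
    selected = frozenset(
        (pair, hemisphere) for pair, hemisphere in cfg.planted_pairs.items()
    )
    module_labels = {
        r: m for m, members in cfg.module_spec.items() for r in members
    }
    return GroundTruth(
        selected_regions=selected,
        module_labels=module_labels,
        hub_regions=frozenset(cfg.hub_spec),
    )


#: Region-level between-module correlation targets of the demo cohort.
#: The sign pattern mirrors the reported inter-network couplings (positive
#: somato-motor/visu, parieto-frontal/temporo-frontal, temporo-frontal with
#: both local networks and posterior-medial/visu; negative parieto-frontal
#: with both local networks and posterior-medial/temporo-frontal; null
#: posterior-medial with somato-motor and parieto-frontal); magnitudes are
#: scaled to what a latent-factor model can carry.
DEMO_BETWEEN_MODULE_R = {
    ("Somato-motor", "Visu"): 0.09,
    ("Parieto-frontal", "Temporo-frontal"): 0.075,
    ("Somato-motor", "Temporo-frontal"): 0.06,
    ("Temporo-frontal", "Visu"): 0.035,
    ("Parieto-frontal", "Somato-motor"): -0.03,
    ("Parieto-frontal", "Visu"): -0.045,
    ("Posterior-medial", "Visu"): 0.03,
    ("Posterior-medial", "Temporo-frontal"): -0.02,
}

#: Connector hubs of the demo cohort: one per network except Visu, each with
#: one secondary module.
DEMO_HUB_SPEC = {
    "f2_2": ("Temporo-frontal",),       # parieto-frontal hub
    "F3t": ("Parieto-frontal",),        # temporo-frontal hub
    "PRECU1": ("Visu",),                # posterior-medial hub
    "cing4": ("Visu",),                 # somato-motor hub
}


def demo_config(rng_seed: int = 0, n_participants: int = 130) -> CohortConfig:
    """Cohort at the study's dimensions, planted with the packaged atlas.

    The 95 atlas regions are planted as the first 95 of 185 homotopic pairs
    (pair id = region abbreviation, favored hemisphere from the atlas); the
    remaining 90 pairs are nulls.  Modules are the atlas's five networks
    (sizes 12/25/23/20/15).
    """
    from .atlas import load_packaged_atlas

    atlas = load_packaged_atlas()
    planted = {r.abbreviation: r.hemisphere for r in atlas}
    null_ids = tuple(f"null{i + 1:03d}" for i in range(185 - len(planted)))
    return CohortConfig(
        n_participants=n_participants,
        n_pairs=185,
        pair_ids=atlas.abbreviations + null_ids,
        planted_pairs=planted,
        module_spec=dict(atlas.network_members()),
        between_module_r=dict(DEMO_BETWEEN_MODULE_R),
        hub_spec=dict(DEMO_HUB_SPEC),
        rng_seed=rng_seed,
    )
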