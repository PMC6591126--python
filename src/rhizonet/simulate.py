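"""Synthetic root-microbiome study generator with planted ground truth.

The generator emulates a three-system field study (conventional, no-till,
organic; 20 farms each) at the scale of a rarefied amplicon survey: an
integer OTU count table whose rows sum exactly to the sequencing depth, a
rank-based taxonomy, and per-farm metadata with soil covariates tied to the
planted signal.

Dependence is induced on latent log-abundances and only then converted to
counts: each "hub module" (one per system that has hubs) carries a latent
environmental gradient; hubs load on it almost perfectly and their partner
taxa ("mids") load moderately, so the pairwise latent correlation between
two members is the product of their loadings. This makes hubs the
highest-degree, best-embedded nodes of the recovered co-occurrence network
— partners reach them through strong associations while partner-partner
associations are mostly too weak to survive FDR — which is exactly the
structure the keystone criteria (high degree, high closeness, low
betweenness) are designed to detect. Background guilds add equicorrelated
blocks in every system, and all remaining OTUs are independent. Latent
values map to compositions by exponentiation and to counts by multinomial
sampling at fixed depth, so the data honor the count/compositional
structure of rarefied tables, and all dependence is rank-based (detectable
by MIC).

Soil covariates are linear functions of the realized summed hub relative
abundance plus Gaussian noise, scaled so each planted covariate explains
roughly half its variance; the agricultural-intensity index is drawn around
a per-system mean. Ground truth (hub identities, guild membership, strongly
dependent pairs, covariate effect sizes) is returned for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "SyntheticTruth", "generate_study", "write_study"]

SYSTEMS = ["conventional", "no_till", "organic"]

HUB_ORDERS = ["Glomerales", "Paraglomerales", "Diversisporales"]
OTHER_ORDERS = [
    "Sordariales",
    "Agaricales",
    "Hypocreales",
    "Cantharellales",
    "Tremellales",
    "Mortierellales",
    "Sebacinales",
    "Malasseziales",
    "Pleosporales",
    "Helotiales",
]

# pairs whose planted latent correlation is at least this are recorded as
# ground-truth dependent (the edges a well-powered analysis should recover)
STRONG_DEPENDENCE = 0.95


@dataclass
class SimConfig:
    """Study design and effect sizes for the synthetic generator.

    Defaults are the emulated study conditions: 3 systems x 20 farms,
    1000 reads/farm, 200 OTUs, planted hubs 0/2/10 by system with loading
    0.99 on their module gradient, partner loadings uniform on
    ``hub_partner_corr``, background guilds equicorrelated at
    ``within_guild_correlation`` within their system's sample block.
    """

    n_samples_per_system: int = 20
    n_otus: int = 200
    reads_per_sample: int = 1000
    n_guilds_per_system: int = 3
    guild_size: int = 8
    n_hubs_per_system: dict = field(
        default_factory=lambda: {"conventional": 0, "no_till": 2, "organic": 10}
    )
    n_strong_partners: int = 0
    n_presence_partners: int = 4
    n_weak_partners: int = 0
    hub_loading: float = 0.998
    strong_partner_corr: tuple = (0.80, 0.88)
    weak_partner_corr: tuple = (0.5, 0.75)
    presence_loading: float = 1.0
    presence_theta_range: tuple = (0.3, 0.7)
    presence_mu: float = 4.6
    hub_amplitude: float = 1.0
    within_guild_correlation: float = 0.9995
    noise_dispersion: float = 1.5
    log_abundance_sd: float = 1.0
    hub_mu: float = 1.0
    mid_mu: float = 0.8
    guild_mu: float = 0.8
    mu_jitter: float = 0.3
    hub_boost: float = 3.1
    mid_boost: float = 2.0
    guild_boost: float = 3.3
    covariate_effects: dict = field(
        default_factory=lambda: {
            "total_p": -1.0,
            "olsen_p": -1.0,
            "ph": 1.0,
            "bulk_density": -1.0,
            "amf_colonization": 1.0,
            "amf_plfa": 0.0,
        }
    )
    intensity_by_system: dict = field(
        default_factory=lambda: {"conventional": 2.5, "no_till": 1.5, "organic": 0.5}
    )
    intensity_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if not 0.0 <= self.within_guild_correlation < 1.0:
            raise ValueError("within_guild_correlation must be in [0, 1)")
        if self.noise_dispersion <= 0:
            raise ValueError("noise_dispersion must be positive")
        needed = sum(
            (n + self.hub_partner_count if n > 0 else 0)
            for n in self.n_hubs_per_system.values()
        ) + len(SYSTEMS) * self.n_guilds_per_system * self.guild_size
        if needed > self.n_otus:
            raise ValueError(
                f"infeasible config: guilds and hub modules need {needed} OTUs "
                f"but n_otus = {self.n_otus}"
            )

    @property
    def hub_partner_count(self) -> int:
        """Partner taxa per hub module (all three partner classes)."""
        return self.n_strong_partners + self.n_presence_partners + self.n_weak_partners

    @classmethod
    def null(cls, n_otus: int = 200, seed: int = 0, **kw) -> "SimConfig":
        """All-independent configuration: no hubs, no guild correlation."""
        return cls(
            n_otus=n_otus,
            n_hubs_per_system={s: 0 for s in SYSTEMS},
            n_guilds_per_system=0,
            within_guild_correlation=0.0,
            seed=seed,
            **kw,
        )


@dataclass
class SyntheticTruth:
    hub_otus: dict  # system -> list of OTU ids
    guild_membership: dict  # OTU id -> guild label
    true_covariate_effects: dict  # covariate -> effect size
    pairwise_dependent: dict  # system -> list of (otu_a, otu_b) strong pairs

    @property
    def all_hubs(self) -> list:
        return [o for hubs in self.hub_otus.values() for o in hubs]

    def to_json(self) -> str:
        out = asdict(self)
        out["pairwise_dependent"] = {
            s: [list(p) for p in pairs] for s, pairs in self.pairwise_dependent.items()
        }
        return json.dumps(out, indent=2)


def _otu_ids(n: int) -> list[str]:
    return [f"OTU_{i + 1:04d}" for i in range(n)]


def generate_study(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate one study: counts, taxonomy, metadata, and ground truth.

    The count table has one row per farm (sample) and sums exactly to
    ``reads_per_sample`` per row; all randomness derives from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_per = config.n_samples_per_system
    n_samples = n_per * len(SYSTEMS)
    n_otus = config.n_otus
    otus = _otu_ids(n_otus)
    sample_ids = [
        f"{sys[:4]}_{i + 1:02d}" for sys in SYSTEMS for i in range(n_per)
    ]
    system_of = np.repeat(SYSTEMS, n_per)

    # --- allocate OTU roles ------------------------------------------------
    cursor = 0
    hub_otus: dict[str, list[str]] = {}
    mids: dict[str, list[str]] = {}
    guild_membership: dict[str, str] = {}
    for sys in SYSTEMS:
        n_hubs = config.n_hubs_per_system.get(sys, 0)
        if n_hubs > 0:
            hub_otus[sys] = otus[cursor : cursor + n_hubs]
            cursor += n_hubs
            mids[sys] = otus[cursor : cursor + config.hub_partner_count]
            cursor += config.hub_partner_count
            for o in hub_otus[sys] + mids[sys]:
                guild_membership[o] = f"{sys}_hub_module"
        else:
            hub_otus[sys] = []
            mids[sys] = []
    guilds: dict[str, list[str]] = {}
    for sys in SYSTEMS:
        for q in range(config.n_guilds_per_system):
            label = f"{sys}_guild_{q + 1}"
            members = otus[cursor : cursor + config.guild_size]
            cursor += config.guild_size
            guilds[label] = members
            for o in members:
                guild_membership[o] = label

    # --- latent log-abundances --------------------------------------------
    # structured OTUs sit above the multinomial noise floor: count noise at
    # the sequencing depth would otherwise swamp the planted rank-dependence
    mu = rng.normal(0.0, config.log_abundance_sd, size=n_otus)
    col = {o: j for j, o in enumerate(otus)}
    for sys in SYSTEMS:
        for o in hub_otus[sys]:
            mu[col[o]] = config.hub_mu + rng.normal(0.0, 0.1)  # tight: hubs stay well above count-noise floor
        for o in mids[sys]:
            mu[col[o]] = config.mid_mu + rng.normal(0.0, config.mu_jitter)
    for members in guilds.values():
        for o in members:
            mu[col[o]] = config.guild_mu + rng.normal(0.0, config.mu_jitter)
    Z = rng.normal(0.0, 1.0, size=(n_samples, n_otus))  # idiosyncratic, unit var

    # hub modules: hubs load ~perfectly on their system's gradient; strong
    # monotone partners load just below the detection range, weak partners
    # add texture, and presence/absence partners occupy samples above (or
    # below) staggered gradient thresholds — a full-entropy 2x2 pattern
    # against any hub, while sharing little information with each other
    from scipy.stats import norm as _norm

    loadings: dict[str, float] = {}
    presence_records: list[tuple[int, np.ndarray, np.ndarray, np.ndarray]] = []
    occupancy_pairs: dict[str, list[tuple[str, str]]] = {s: [] for s in SYSTEMS}
    for sys in SYSTEMS:
        if not hub_otus[sys]:
            continue
        in_sys = system_of == sys
        # fixed-spread gradient: farms span the environmental range by
        # design, so the module's signal strength does not swing with the
        # luck of an iid draw
        m_sys = in_sys.sum()
        gradient = rng.permutation(_norm.ppf((np.arange(m_sys) + 0.5) / m_sys))
        # hubs respond steeply to the gradient: a staircase with jumps at
        # the same thresholds that bound the presence partners' niches, so
        # hub counts separate cleanly across every occupancy boundary
        lo_t, hi_t = config.presence_theta_range
        n_pres = config.n_presence_partners
        thetas = np.linspace(lo_t, hi_t, n_pres) if n_pres else np.array([])
        grad_rank = _norm.cdf(gradient)
        segment = np.searchsorted(thetas, grad_rank).astype(float)
        if segment.std() > 0:
            segment = (segment - segment.mean()) / segment.std()
        # damped amplitude bounds the module's compositional footprint while
        # keeping clean count separation across every occupancy boundary
        staircase = (
            config.hub_amplitude * segment if n_pres else config.hub_amplitude * gradient
        )
        for o in hub_otus[sys]:
            loadings[o] = config.hub_loading
        part = mids[sys]
        strong = part[: config.n_strong_partners]
        presence = part[
            config.n_strong_partners : config.n_strong_partners
            + config.n_presence_partners
        ]
        weak = part[config.n_strong_partners + config.n_presence_partners :]
        for i, o in enumerate(strong):
            sign = 1.0 if i % 2 == 0 else -1.0  # negative associates balance reads
            loadings[o] = sign * rng.uniform(*config.strong_partner_corr)
        for o in weak:
            loadings[o] = rng.uniform(*config.weak_partner_corr)
        for o in strong + weak:
            b = loadings[o]
            j = col[o]
            Z[in_sys, j] = b * gradient + np.sqrt(max(1 - b * b, 0.0)) * Z[in_sys, j]
        for i, o in enumerate(hub_otus[sys]):
            b = loadings[o]
            j = col[o]
            # alternating orientation: half the hubs climb the gradient and
            # half descend it, so the module's total read share stays flat
            # (no compositional ramp imprinted on unrelated taxa); pairwise
            # hub dependence is unchanged in magnitude
            sign = 1.0 if i % 2 == 0 else -1.0
            Z[in_sys, j] = sign * b * staircase + np.sqrt(max(1 - b * b, 0.0)) * Z[in_sys, j]
        for k, o in enumerate(presence):
            bl = config.presence_loading
            u_k = bl * gradient + np.sqrt(1 - bl * bl) * rng.normal(
                0.0, 1.0, size=in_sys.sum()
            )
            cut = _norm.ppf(thetas[k])
            present = (u_k > cut) if k % 2 == 0 else (u_k < cut)
            # flat, rich occupied abundance: the partner keeps a clear
            # margin over the multinomial noise floor even in samples where
            # the hub module swells and total weight is large; a flat level
            # (rather than one tracking the gradient) keeps partner pairs
            # free of any shared monotone component
            logw = np.full(m_sys, config.presence_mu)
            presence_records.append((col[o], in_sys, present, logw))
            loadings[o] = 0.0  # occupancy-coupled, not loading-coupled
            occupancy_pairs[sys].extend((h, o) for h in hub_otus[sys])
            mu[col[o]] = 1.0 + rng.normal(0.0, config.mu_jitter)  # out-of-system baseline

    rho = config.within_guild_correlation
    for label, members in guilds.items():
        sys = label.rsplit("_guild_", 1)[0]
        in_sys = system_of == sys
        if rho <= 0:
            continue
        m_sys = in_sys.sum()
        f = rng.permutation(_norm.ppf((np.arange(m_sys) + 0.5) / m_sys))
        for i, o in enumerate(members):
            j = col[o]
            # mostly-positive loads with a negative minority: keeps the
            # guild's read share from swinging coherently (compositional
            # closure would otherwise wire unrelated blocks together) while
            # |within-guild correlation| stays rho for every pair
            sign = -1.0 if i % 4 == 3 else 1.0
            Z[in_sys, j] = 0.85 * (
                sign * np.sqrt(rho) * f + np.sqrt(1 - rho) * Z[in_sys, j]
            )
            loadings.setdefault(o, np.sqrt(rho))

    # differential abundance of module members in their own system
    boost = np.zeros((n_samples, n_otus))
    for sys in SYSTEMS:
        in_sys = system_of == sys
        for o in hub_otus[sys]:
            boost[in_sys, col[o]] = config.hub_boost
        for o in mids[sys]:
            boost[in_sys, col[o]] = config.mid_boost
    for label, members in guilds.items():
        sys = label.rsplit("_guild_", 1)[0]
        in_sys = system_of == sys
        for o in members:
            boost[in_sys, col[o]] = config.guild_boost

    log_abund = mu[None, :] + boost + config.noise_dispersion * Z
    weights = np.exp(log_abund)
    # presence/absence partners: structural zeros when unoccupied, high
    # abundance when occupied (within their system's sample block only)
    for j, in_sys, present, logw in presence_records:
        occupied_w = np.exp(logw + 0.3 * rng.normal(0.0, 1.0, size=in_sys.sum()))
        weights[in_sys, j] = np.where(present, occupied_w, 0.0)
    probs = weights / weights.sum(axis=1, keepdims=True)

    counts = np.empty((n_samples, n_otus), dtype=np.int64)
    for i in range(n_samples):
        counts[i] = rng.multinomial(config.reads_per_sample, probs[i])
    table = pd.DataFrame(counts, index=sample_ids, columns=otus)

    # --- taxonomy ----------------------------------------------------------
    orders = []
    hub_set = {o for hubs in hub_otus.values() for o in hubs}
    k_hub = 0
    for j, o in enumerate(otus):
        if o in hub_set:
            orders.append(HUB_ORDERS[k_hub % len(HUB_ORDERS)])
            k_hub += 1
        else:
            orders.append(OTHER_ORDERS[rng.integers(len(OTHER_ORDERS))])
    taxonomy = pd.DataFrame(
        {
            "kingdom": "Fungi",
            "phylum": ["Glomeromycota" if o in HUB_ORDERS else "Ascomycota" for o in orders],
            "class": "",
            "order": orders,
            "family": "",
            "genus": [f"Genus_{j + 1}" for j in range(n_otus)],
        },
        index=pd.Index(otus, name="otu"),
    )

    # --- metadata ----------------------------------------------------------
    hub_cols = [col[o] for o in sorted(hub_set, key=otus.index)]
    if hub_cols:
        hub_rel = counts[:, hub_cols].sum(axis=1) / config.reads_per_sample
        sd = hub_rel.std()
        hub_std = (hub_rel - hub_rel.mean()) / (sd if sd > 0 else 1.0)
    else:
        hub_std = np.zeros(n_samples)
    cov_centers = {
        "total_p": (800.0, 200.0),
        "olsen_p": (30.0, 12.0),
        "ph": (6.5, 0.5),
        "bulk_density": (1.35, 0.12),
        "amf_colonization": (40.0, 14.0),
        "amf_plfa": (5.0, 1.8),
    }
    md = {
        "system": system_of,
        "region": np.tile(["northeast", "southwest"], n_samples)[:n_samples],
        "intensity_index": np.array(
            [
                config.intensity_by_system[s] for s in system_of
            ]
        )
        + rng.normal(0.0, config.intensity_sd, size=n_samples),
    }
    for name, (center, unit_sd) in cov_centers.items():
        beta = config.covariate_effects.get(name, 0.0)
        raw = beta * hub_std + rng.normal(0.0, 1.0, size=n_samples)
        md[name] = center + unit_sd * raw / np.sqrt(beta**2 + 1.0)
    metadata = pd.DataFrame(md, index=pd.Index(sample_ids, name="sample"))

    # --- ground truth ------------------------------------------------------
    # strong pairs: planted latent correlation at or above STRONG_DEPENDENCE
    # (hub-hub pairs at default loadings; guild pairs only if rho qualifies)
    pairwise: dict[str, list[tuple[str, str]]] = {s: [] for s in SYSTEMS}
    for sys in SYSTEMS:
        members = hub_otus[sys] + mids[sys]
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                a, b = members[a_i], members[b_i]
                if abs(loadings[a] * loadings[b]) >= STRONG_DEPENDENCE:
                    pairwise[sys].append((a, b))
        pairwise[sys].extend(occupancy_pairs[sys])
    for label, members in guilds.items():
        sys = label.rsplit("_guild_", 1)[0]
        if rho >= STRONG_DEPENDENCE:
            for a_i in range(len(members)):
                for b_i in range(a_i + 1, len(members)):
                    pairwise[sys].append((members[a_i], members[b_i]))
    truth = SyntheticTruth(
        hub_otus=hub_otus,
        guild_membership=guild_membership,
        true_covariate_effects=dict(config.covariate_effects),
        pairwise_dependent=pairwise,
    )
    return table, taxonomy, metadata, truth


def write_study(outdir, table, taxonomy, metadata, truth) -> None:
    """Write the three tables as TSV and the ground truth as JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "otu_table.tsv", sep="\t")
    taxonomy.to_csv(outdir / "taxonomy.tsv", sep="\t")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    (outdir / "truth.json").write_text(truth.to_json())
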