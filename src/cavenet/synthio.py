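"""Synthetic community tables with planted ground truth.

The generator emulates the downstream products of an amplicon study of cave
weathered-rock communities: a sparse, over-dispersed, compositional count
table (features x samples), a taxonomy map, and sample metadata with
environmental gradients tied to designated modules.

Mechanism: each planted module m has a latent Gaussian factor f_m per
sample.  Features in module m load on f_m (loading tuned so same-module
pairs reach the target rank correlation), a configurable fraction load
negatively, and planted connector features load evenly on several modules.
Per-feature log-abundances pass through a softmax to per-sample
compositions, and counts are multinomial draws at a random depth.
Environmental variables are linear in module factors plus unit noise, so a
variable with effect size 0 is pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .tables import FeatureTable, SampleMetadata, TaxonomyMap

__all__ = ["SynSpec", "SynTruth", "generate", "truth_metrics"]

# clade labels seen in cave methanotroph/bacteria surveys; the first covers
# the dominant module
_LABEL_POOL = (
    "USCgamma",
    "USCalpha",
    "Deep-sea_2",
    "JRC-3",
    "JRC-1",
    "Deep-sea_4",
    "RPC",
    "TUSC",
    "Gaiella",
    "Aciditerrimonas",
    "Methyloceanibacter",
    "Methylomirabilis",
)

#: default environmental gradients: (variable, affected module, effect size).
#: a variable may appear several times, once per module it drives (a pH
#: gradient shapes several clades at once; a single-module gradient is
#: nearly invisible in a community-wide Bray-Curtis comparison).
#: pH and CH4 track the two largest modules, CO2 a third, Cl- is pure noise.
DEFAULT_ENV_EFFECTS = (
    ("pH", 0, 2.5),
    ("CH4_ppm", 0, 2.5),
    ("CO2_ppm", 1, 1.5),
    ("Cl", 0, 0.0),
)


@dataclass(frozen=True)
class SynSpec:
    """Parameters of one synthetic community draw.

    Defaults mirror the study scale: 36 samples, ~900 features in 11 planted
    modules, sequencing depths around 10^4 reads.
    """

    n_features: int = 900
    n_samples: int = 36
    n_modules: int = 11
    within_module_rho: float = 0.85
    n_connectors: int = 3
    connector_span: int = 3
    depth_range: tuple[int, int] = (8000, 12000)
    dispersion: float = 1.0
    env_effects: tuple[tuple[str, int, float], ...] = DEFAULT_ENV_EFFECTS
    negative_assoc_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules < 1:
            raise ValueError("need at least one module")
        if not 0 < self.within_module_rho < 1:
            raise ValueError("within_module_rho must be in (0, 1)")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth range must be positive and ordered")
        if not 0 <= self.negative_assoc_fraction <= 1:
            raise ValueError("negative_assoc_fraction must be in [0, 1]")
        if self.connector_span > self.n_modules:
            raise ValueError("connectors cannot span more modules than exist")
        if self.n_features < self.n_modules + self.n_connectors:
            raise ValueError("too few features for the requested modules/connectors")
        for var, module, _ in self.env_effects:
            if not 0 <= module < self.n_modules:
                raise ValueError(f"env effect {var!r} targets unknown module {module}")


@dataclass
class SynTruth:
    """Planted ground truth accompanying a generated table."""

    partition: dict[str, int]  # module members only (connectors listed apart)
    connectors: list[str]
    connector_modules: dict[str, tuple[int, ...]]
    association: pd.DataFrame  # signed feature x feature latent associations
    env_gradients: pd.DataFrame  # sample x module latent factor values
    feature_signs: dict[str, int]

    def __post_init__(self) -> None:
        a = self.association.to_numpy()
        if not np.array_equal(a, a.T):
            raise ValueError("association matrix must be symmetric")


def _module_sizes(n: int, n_modules: int) -> list[int]:
    # mildly dominant first module (it carries the environmental gradients);
    # stronger dominance would let its factor swing the compositional
    # denominator, which both dampens the module's own within-correlations
    # and induces spurious negative correlations elsewhere
    weights = np.array([1.5] + [1.0] * (n_modules - 1))
    sizes = np.floor(n * weights / weights.sum()).astype(int)
    sizes = np.maximum(sizes, 1)
    sizes[0] += n - sizes.sum()
    return sizes.tolist()


def generate(
    spec: SynSpec,
) -> tuple[FeatureTable, TaxonomyMap, SampleMetadata, SynTruth]:
    """Draw one synthetic dataset; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_mod_features = spec.n_features - spec.n_connectors
    sizes = _module_sizes(n_mod_features, spec.n_modules)

    feature_ids = [f"F{i:04d}" for i in range(spec.n_features)]
    module_of: dict[str, int] = {}
    pos = 0
    for mid, size in enumerate(sizes):
        for fid in feature_ids[pos : pos + size]:
            module_of[fid] = mid
        pos += size
    connectors = feature_ids[pos:]
    connector_modules = {
        fid: tuple(sorted(rng.choice(spec.n_modules, spec.connector_span, replace=False)))
        for fid in connectors
    }

    # latent Pearson correlation that yields the target Spearman rho for a
    # bivariate Gaussian: r = 2 sin(pi * rho / 6)
    r = 2.0 * np.sin(np.pi * spec.within_module_rho / 6.0)
    loading = np.sqrt(r)
    noise_sd = np.sqrt(1.0 - r)

    factors = rng.standard_normal((spec.n_modules, spec.n_samples))
    signs = {
        fid: -1 if rng.random() < spec.negative_assoc_fraction else 1
        for fid in feature_ids
    }
    for fid in connectors:
        signs[fid] = 1  # connectors bridge modules with positive links

    base = rng.normal(0.0, 1.2, size=spec.n_features)  # lognormal abundance spread
    for i, fid in enumerate(feature_ids):
        if fid in connector_modules:
            # connectors are abundant taxa: zero-inflated counts would drown
            # their (already ceiling-limited) cross-module correlations
            base[i] = 2.0
    signal = np.empty((spec.n_features, spec.n_samples))
    for i, fid in enumerate(feature_ids):
        eps = rng.standard_normal(spec.n_samples) * noise_sd
        if fid in connector_modules:
            # connectors carry no idiosyncratic noise: their signal is the
            # even mix of spanned-module factors, which already caps their
            # per-module correlation at 1/sqrt(span)
            span = connector_modules[fid]
            signal[i] = factors[list(span)].sum(axis=0) / np.sqrt(len(span))
        else:
            signal[i] = signs[fid] * loading * factors[module_of[fid]] + eps

    log_abund = base[:, np.newaxis] + spec.dispersion * signal
    comp = np.exp(log_abund - log_abund.max(axis=0, keepdims=True))
    comp /= comp.sum(axis=0, keepdims=True)

    depths = rng.integers(spec.depth_range[0], spec.depth_range[1] + 1, spec.n_samples)
    counts = np.empty((spec.n_features, spec.n_samples), dtype=np.int64)
    for j in range(spec.n_samples):
        counts[:, j] = rng.multinomial(depths[j], comp[:, j])

    sample_ids = [f"S{j:02d}" for j in range(spec.n_samples)]
    table = FeatureTable(feature_ids, sample_ids, counts)

    # taxonomy: one label blankets the dominant module; connectors carry it
    # too (keystone candidates), remaining modules cycle through the pool
    lineages = {}
    for fid in feature_ids:
        if fid in connector_modules:
            label = _LABEL_POOL[0]
        else:
            label = _LABEL_POOL[module_of[fid] % len(_LABEL_POOL)]
        lineages[fid] = ("Bacteria", label)
    taxonomy = TaxonomyMap(lineages)

    # metadata: gradients linear in module factors, plus the cave/site/niche
    # design of 3 caves x 2 sites x 2 niches
    meta = {}
    for var, module, effect in spec.env_effects:
        signal_part = effect * factors[module]
        if var in meta:
            meta[var] = meta[var] + signal_part  # same variable, another module
        else:
            meta[var] = signal_part + rng.standard_normal(spec.n_samples)
    mdf = pd.DataFrame(meta, index=sample_ids)
    caves = ["PLD", "LHD", "XCT"]
    mdf["cave"] = [caves[j % 3] for j in range(spec.n_samples)]
    mdf["site"] = [f"site{(j // 3) % 2 + 1}" for j in range(spec.n_samples)]
    mdf["niche"] = ["rock" if (j // 6) % 2 == 0 else "crust" for j in range(spec.n_samples)]
    metadata = SampleMetadata(mdf)

    assoc = np.zeros((spec.n_features, spec.n_features))
    idx = {fid: i for i, fid in enumerate(feature_ids)}
    by_module: dict[int, list[str]] = {}
    for fid, mid in module_of.items():
        by_module.setdefault(mid, []).append(fid)
    for members in by_module.values():
        for a in members:
            for b in members:
                if a != b:
                    assoc[idx[a], idx[b]] = signs[a] * signs[b]
    for fid, span in connector_modules.items():
        for mid in span:
            for b in by_module[mid]:
                s = signs[fid] * signs[b]
                assoc[idx[fid], idx[b]] = s
                assoc[idx[b], idx[fid]] = s

    truth = SynTruth(
        partition=dict(module_of),
        connectors=list(connectors),
        connector_modules=connector_modules,
        association=pd.DataFrame(assoc, index=feature_ids, columns=feature_ids),
        env_gradients=pd.DataFrame(
            factors.T, index=sample_ids, columns=[f"module_{m}" for m in range(spec.n_modules)]
        ),
        feature_signs=dict(signs),
    )
    return table, taxonomy, metadata, truth


def truth_metrics(
    truth: SynTruth,
    inferred_partition: list[set] | None = None,
    inferred_net: nx.Graph | None = None,
    roles: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Recovery scores of inferred structure against the planted truth.

    * ``partition_ari`` — adjusted Rand index between the planted and the
      inferred partition, over the nodes both cover (connectors excluded,
      since they have no single true module).
    * ``edge_precision`` / ``edge_recall`` — inferred edges against non-zero
      latent associations.
    * ``connector_recall`` — fraction of planted connectors present in the
      role table that are classified as connectors.
    """
    out: dict[str, float] = {}
    if inferred_partition is not None:
        owner = {}
        for mid, members in enumerate(inferred_partition):
            for v in members:
                owner[v] = mid
        common = [f for f in truth.partition if f in owner]
        if not common:
            raise ValueError("no shared ids between truth and inferred partition")
        out["partition_ari"] = float(
            adjusted_rand_score(
                [truth.partition[f] for f in common], [owner[f] for f in common]
            )
        )
    if inferred_net is not None:
        ids = set(truth.association.index)
        edges = {
            frozenset((u, v)) for u, v in inferred_net.edges if u in ids and v in ids
        }
        a = truth.association
        true_pairs = {
            frozenset((a.index[i], a.columns[j]))
            for i, j in zip(*np.nonzero(a.to_numpy()))
            if i < j
        }
        tp = len(edges & true_pairs)
        out["edge_precision"] = tp / len(edges) if edges else 0.0
        out["edge_recall"] = tp / len(true_pairs) if true_pairs else 0.0
    if roles is not None:
        present = [f for f in truth.connectors if f in roles.index]
        if present:
            hit = sum(roles.loc[f, "role"] == "connector" for f in present)
            out["connector_recall"] = hit / len(present)
        else:
            out["connector_recall"] = 0.0
    return out
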