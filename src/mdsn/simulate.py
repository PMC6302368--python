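"""Synthetic sample-matched miRNA/mRNA cohorts with planted dysregulation modules.

The generator emulates the structure the pipeline is designed to detect:
groups ("modules") of miRNAs that repress a shared, module-specific target
set with a correlation strength that differs between subtypes, plus stage
labels driven by the expression of a subset of modules.

Correlation is induced by one latent standard-normal factor per
(module, sample): a miRNA in module m loads sqrt(|rho|) on the factor and a
target of m loads sign(rho)*sqrt(|rho|), so each planted (miRNA, target)
pair has population correlation rho while within-module miRNA-miRNA
expression correlation is |rho| (harmless — the pipeline never uses
miRNA-miRNA expression correlation). Background features are independent
standard normals. Values are generated directly on the standardized
(post-preprocessing) scale; ``to_raw_scale`` inverts the log2/z-transform to
produce raw-abundance fixtures for exercising ``preprocess_expression``.

Stage labels follow an ordinal-logistic model on the mean expression of the
relevant modules' miRNAs: latent u = effect_size * mean + logistic noise,
cut at the standard-logistic quantiles that make classes roughly balanced
under the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .communities import ModulePartition
from .errors import ParameterError
from .io import ExpressionMatrix, GroupDesign

STAGE_LABELS = ("normal", "I", "II", "III", "IV")


@dataclass
class PlantedStructure:
    """Ground truth of a simulated cohort, for testing downstream stages."""

    module_of: dict[str, int]
    targets_of_module: dict[int, set]
    corr_by_subtype: dict[tuple[int, str], float]
    relevant_modules: set = field(default_factory=set)
    effect_size: float = 0.0

    def __post_init__(self):
        for (m, sub), rho in self.corr_by_subtype.items():
            if not abs(rho) < 1:
                raise ParameterError(f"|rho| must be < 1; got {rho} for module {m}, subtype {sub}")
        seen = {}
        for m, targets in self.targets_of_module.items():
            for t in targets:
                if t in seen and seen[t] != m:
                    # default generator keeps target sets disjoint; overlap is
                    # permitted when constructed explicitly
                    break
                seen[t] = m

    def planted_pairs(self) -> list[tuple[str, str, int]]:
        """(mirna, target, module) for every planted regulatory pair."""
        out = []
        for mi, m in self.module_of.items():
            for t in self.targets_of_module.get(m, ()):
                out.append((mi, t, m))
        return out


def simulate_cohort(
    n_mirna: int = 100,
    n_mrna: int = 300,
    n_modules: int = 4,
    subtype_sizes: dict[str, int] | None = None,
    corr_scheme: dict[tuple[int, str], float] | None = None,
    stage_classes: int = 5,
    effect_size: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    mirnas_per_module: int = 10,
    targets_per_module: int = 25,
    n_relevant_modules: int = 2,
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroupDesign, PlantedStructure]:
    """Simulate a sample-matched miRNA/mRNA cohort with planted modules.

    Defaults plant 4 modules of 10 miRNAs with 25 disjoint targets each,
    repressing (rho = -0.8) in the first subtype and silent (rho = 0) in the
    second — the regime where a dysregulation analysis between the two
    subtypes should light up exactly the planted pairs. Subtype sizes
    default to 60 per subtype; 5 ordinal stage classes driven by the first
    ``n_relevant_modules`` modules. Fully deterministic given ``seed``.

    ``corr_scheme`` maps (module_index, subtype_label) -> rho and overrides
    the default; missing entries mean rho = 0.
    """
    if min(n_mirna, n_mrna, n_modules, stage_classes) <= 0:
        raise ParameterError("all counts must be positive")
    if n_modules * mirnas_per_module > n_mirna:
        raise ParameterError("not enough miRNAs for the requested modules")
    if n_modules * targets_per_module > n_mrna:
        raise ParameterError("not enough mRNAs for the requested disjoint target sets")
    if subtype_sizes is None:
        subtype_sizes = {"alpha": 60, "beta": 60}
    if any(n < 4 for n in subtype_sizes.values()):
        raise ParameterError("every subtype needs >= 4 samples (Fisher test requires n-3 > 0)")
    subtypes = list(subtype_sizes)
    if corr_scheme is None:
        corr_scheme = {(m, subtypes[0]): -0.8 for m in range(n_modules)}
    for (m, sub), rho in corr_scheme.items():
        if not abs(rho) < 1:
            raise ParameterError(f"unreachable correlation rho={rho} for module {m}, {sub}")

    rng = np.random.default_rng(seed)
    mirna_ids = [f"mir-{i:04d}" for i in range(n_mirna)]
    mrna_ids = [f"gene-{j:04d}" for j in range(n_mrna)]
    module_of = {
        mirna_ids[m * mirnas_per_module + k]: m
        for m in range(n_modules)
        for k in range(mirnas_per_module)
    }
    targets_of_module = {
        m: {mrna_ids[m * targets_per_module + k] for k in range(targets_per_module)}
        for m in range(n_modules)
    }
    relevant = set(range(min(n_relevant_modules, n_modules)))

    n_samples = sum(subtype_sizes.values())
    sample_ids = []
    subtype_of = {}
    for sub, n in subtype_sizes.items():
        for k in range(len(sample_ids), len(sample_ids) + n):
            sid = f"sample-{k:04d}"
            sample_ids.append(sid)
            subtype_of[sid] = sub
    subtype_arr = np.array([subtype_of[s] for s in sample_ids])

    # independent background for everything, then overwrite planted features
    x = rng.standard_normal((n_mirna, n_samples))
    y = rng.standard_normal((n_mrna, n_samples))
    mirna_idx = {mid: i for i, mid in enumerate(mirna_ids)}
    mrna_idx = {gid: j for j, gid in enumerate(mrna_ids)}

    factors = rng.standard_normal((n_modules, n_samples))
    for m in range(n_modules):
        rho_of_sample = np.array(
            [corr_scheme.get((m, sub), 0.0) for sub in subtype_arr]
        )
        a = np.sqrt(np.abs(rho_of_sample))  # miRNA-side loading
        b = np.sign(rho_of_sample) * a  # target-side loading carries the sign
        resid = np.sqrt(1.0 - a**2)
        f = factors[m]
        for mid, mod in module_of.items():
            if mod != m:
                continue
            i = mirna_idx[mid]
            x[i] = a * f + resid * rng.standard_normal(n_samples)
        for gid in sorted(targets_of_module[m]):
            j = mrna_idx[gid]
            y[j] = b * f + resid * rng.standard_normal(n_samples)

    # ordinal stage labels from the relevant-module miRNA mean
    rel_rows = [mirna_idx[mid] for mid, m in module_of.items() if m in relevant]
    signal = x[rel_rows].mean(axis=0) if rel_rows else np.zeros(n_samples)
    u = effect_size * signal + noise_sd * rng.logistic(size=n_samples)
    # cutpoints at standard-logistic quantiles -> balanced classes at effect 0
    qs = np.arange(1, stage_classes) / stage_classes
    cuts = noise_sd * np.log(qs / (1 - qs))
    stage_idx = np.searchsorted(cuts, u)
    labels = list(STAGE_LABELS[:stage_classes])
    if stage_classes > len(STAGE_LABELS):
        labels = [f"class{c}" for c in range(stage_classes)]
    stage_of = {s: labels[c] for s, c in zip(sample_ids, stage_idx)}

    mirna = ExpressionMatrix(mirna_ids, sample_ids, x, processed=True)
    mrna = ExpressionMatrix(mrna_ids, sample_ids, y, processed=True)
    design = GroupDesign(sample_ids, subtype_of, stage_of, tuple(labels))
    truth = PlantedStructure(
        module_of=module_of,
        targets_of_module=targets_of_module,
        corr_by_subtype=dict(corr_scheme),
        relevant_modules=relevant,
        effect_size=effect_size,
    )
    return mirna, mrna, design, truth


def to_raw_scale(m: ExpressionMatrix, pseudocount: float = 1.0, scale: float = 2.0, center: float = 6.0) -> ExpressionMatrix:
    """Invert the log2/z transform to produce a raw-abundance fixture.

    Treats each standardized value as a log2 abundance z*scale + center and
    returns 2**(that) - pseudocount clipped at 0, so preprocess_expression
    approximately recovers the standardized matrix.
    """
    raw = np.clip(np.exp2(m.values * scale + center) - pseudocount, 0.0, None)
    return ExpressionMatrix(list(m.feature_ids), list(m.sample_ids), raw, processed=False)


def ground_truth_partition(ps: PlantedStructure) -> ModulePartition:
    """Reference partition of planted-module miRNAs (miRNAs with no module excluded)."""
    assignment = {mid: m for mid, m in ps.module_of.items() if m is not None}
    return ModulePartition(assignment=assignment, modularity=float("nan"), levels=[], seed=None)
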