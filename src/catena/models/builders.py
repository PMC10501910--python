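"""Declarative builders for every study model family.

Conventions shared by all builders: the first indicator's loading is
fixed to 1 to set each latent's scale; intercepts of indicators are
free; latent means are fixed at 0 unless a builder frees them; key
association parameters carry stable labels (``cov.*``, ``beta.*``,
``stab.*``, ``chg*``) so reports and tests can address them.  In
multi-group builds the label gains a ``.<group>`` suffix.
"""

from __future__ import annotations

from ..sem.model import ModelSpec
from .design import (
    DesignError,
    StudyDesign,
    cognitive_indicator,
    neural_avg_indicator,
    neural_indicator,
)

COG_FACTORS = ("wm", "em", "gf")


def _glabel(base: str, group: str | None, multigroup: bool) -> str:
    return f"{base}.{group}" if multigroup else base


def _each_group(spec: ModelSpec):
    """(group-arg, label-suffix flag) pairs: one per group if multi-group."""
    if len(spec.groups) > 1:
        return [(g, True) for g in spec.groups]
    return [(None, False)]


def _measurement_block(
    spec: ModelSpec, latent: str, indicators: list[str],
    fix_all_loadings: bool = False,
) -> None:
    for i, y in enumerate(indicators):
        if i == 0 or fix_all_loadings:
            spec.add("loading", y, latent, free=False, value=1.0)
        else:
            spec.add("loading", y, latent)


def _observed_block(spec: ModelSpec, indicators: list[str]) -> None:
    for y in indicators:
        spec.add("variance", y, y)
        spec.add("mean", y)


# -- modality-specific factor model -------------------------------------------


def build_modality_factor_model(
    region: str,
    timepoint: int,
    design: StudyDesign | None = None,
    groups: tuple[str, ...] | None = None,
) -> ModelSpec:
    """One latent per available modality, left/right hemispheric indicators,
    free pairwise covariances among the modality factors."""
    design = design or StudyDesign()
    design.validate()
    mods = design.region_modalities(region, timepoint)
    groups = tuple(groups) if groups else ("all",)
    observed, latents = [], []
    for mod in mods:
        latents.append(f"{region}_{mod}")
        observed += [
            neural_indicator(region, mod, h, timepoint) for h in ("left", "right")
        ]
    spec = ModelSpec(observed=observed, latent=latents, groups=list(groups))
    for mod, lv in zip(mods, latents):
        inds = [neural_indicator(region, mod, h, timepoint) for h in ("left", "right")]
        _measurement_block(spec, lv, inds)
        spec.add("variance", lv, lv)
    _observed_block(spec, observed)
    multi = len(groups) > 1
    for i, a in enumerate(latents):
        for b in latents[i + 1:]:
            for g, suff in _each_group(spec):
                spec.add("covariance", a, b, group=g,
                         label=_glabel(f"cov.{a}.{b}", g, suff))
    spec.validate()
    return spec


# -- multimodal (second-order) model ------------------------------------------


def build_multimodal_model(
    region: str,
    timepoint: int,
    design: StudyDesign | None = None,
    groups: tuple[str, ...] | None = None,
    joint: bool = False,
) -> ModelSpec:
    """Second-order integrity factor over the modality-specific factors.

    With two first-order factors both second-order loadings are fixed to
    1; with three or more, the first is fixed and the rest are free.
    With ``joint=True`` both regions are built in one model and the
    covariance between their multimodal factors is estimated.
    """
    design = design or StudyDesign()
    design.validate()
    regions = design.regions if joint else (region,)
    groups = tuple(groups) if groups else ("all",)
    spec = ModelSpec(observed=[], latent=[], groups=list(groups))
    multi_factors = []
    for reg in regions:
        mods = design.region_modalities(reg, timepoint)
        if len(mods) < 2:
            raise DesignError(
                f"multimodal factor for {reg!r} needs >= 2 modalities, got {len(mods)}"
            )
        first_order = []
        for mod in mods:
            lv = f"{reg}_{mod}"
            first_order.append(lv)
            inds = [neural_indicator(reg, mod, h, timepoint) for h in ("left", "right")]
            spec.observed += inds
            spec.latent.append(lv)
            _measurement_block(spec, lv, inds)
            spec.add("variance", lv, lv)  # modality-specific residual variance
            _observed_block(spec, inds)
        top = f"{reg}_multi"
        spec.latent.append(top)
        fix_all = len(first_order) == 2
        for i, lv in enumerate(first_order):
            if i == 0 or fix_all:
                spec.add("loading", lv, top, free=False, value=1.0)
            else:
                for g, suff in _each_group(spec):
                    spec.add("loading", lv, top, group=g,
                             label=_glabel(f"load.{top}.{lv}", g, suff))
        for g, suff in _each_group(spec):
            spec.add("variance", top, top, group=g,
                     label=_glabel(f"var.{top}", g, suff))
        multi_factors.append(top)
    if len(multi_factors) == 2:
        a, b = multi_factors
        for g, suff in _each_group(spec):
            spec.add("covariance", a, b, group=g,
                     label=_glabel(f"cov.{a}.{b}", g, suff))
    spec.validate()
    return spec


# -- cognitive three-factor model ---------------------------------------------


def build_cognitive_model(
    timepoint: int,
    design: StudyDesign | None = None,
    groups: tuple[str, ...] | None = None,
) -> ModelSpec:
    """Correlated WM/EM/Gf latents over the fixed 10-task map."""
    design = design or StudyDesign()
    design.validate()
    groups = tuple(groups) if groups else ("all",)
    spec = ModelSpec(observed=[], latent=list(COG_FACTORS), groups=list(groups))
    for factor in COG_FACTORS:
        inds = [cognitive_indicator(t, timepoint) for t in design.task_map[factor]]
        spec.observed += inds
        _measurement_block(spec, factor, inds)
        spec.add("variance", factor, factor)
        _observed_block(spec, inds)
    for i, a in enumerate(COG_FACTORS):
        for b in COG_FACTORS[i + 1:]:
            for g, suff in _each_group(spec):
                spec.add("covariance", a, b, group=g,
                         label=_glabel(f"cov.{a}.{b}", g, suff))
    spec.validate()
    return spec


# -- unified neurocognitive model ---------------------------------------------


def build_neurocognitive_model(
    variant: str,
    timepoint: int = 2,
    design: StudyDesign | None = None,
    regions: tuple[str, ...] | None = None,
    include_mtl: bool = False,
    groups: tuple[str, ...] | None = None,
) -> ModelSpec:
    """Joint neural + cognitive model.

    ``variant='correlation'``: free covariances between every neural
    (multimodal) factor and every cognitive factor.  ``'regression'``:
    directed paths from each neural factor to each cognitive factor, with
    free residual covariances among the cognitive factors.  The two
    variants are statistically equivalent reparameterisations.
    """
    if variant not in ("correlation", "regression"):
        raise DesignError(f"unknown neurocognitive variant {variant!r}")
    design = design or StudyDesign()
    regions = tuple(regions) if regions else design.regions
    groups = tuple(groups) if groups else ("all",)
    joint = len(regions) == 2
    spec = build_multimodal_model(
        regions[0], timepoint, design, groups, joint=joint
    )
    neural = [f"{r}_multi" for r in regions]
    # append the cognitive measurement part
    for factor in COG_FACTORS:
        inds = [cognitive_indicator(t, timepoint) for t in design.task_map[factor]]
        spec.observed += inds
        spec.latent.append(factor)
        _measurement_block(spec, factor, inds)
        spec.add("variance", factor, factor)
        _observed_block(spec, inds)
    if include_mtl:
        neural.append(_add_mtl_block(spec))
    multi = len(groups) > 1
    for i, a in enumerate(COG_FACTORS):
        for b in COG_FACTORS[i + 1:]:
            for g, suff in _each_group(spec):
                label = ("cov" if variant == "correlation" else "rcov")
                spec.add("covariance", a, b, group=g,
                         label=_glabel(f"{label}.{a}.{b}", g, suff))
    if variant == "correlation":
        for nf in neural:
            for cf in COG_FACTORS:
                for g, suff in _each_group(spec):
                    spec.add("covariance", nf, cf, group=g,
                             label=_glabel(f"cov.{nf}.{cf}", g, suff))
    else:
        for cf in COG_FACTORS:
            for nf in neural:
                for g, suff in _each_group(spec):
                    spec.add("regression", cf, nf, group=g,
                             label=_glabel(f"beta.{cf}.{nf}", g, suff))
    spec.validate()
    return spec


def _add_mtl_block(spec: ModelSpec) -> str:
    """Higher-order MTL factor over hippocampal/parahippocampal factors."""
    for reg in ("hippocampus", "parahippocampus"):
        inds = [f"{reg}_{h}" for h in ("left", "right")]
        spec.observed += inds
        spec.latent.append(reg)
        _measurement_block(spec, reg, inds)
        spec.add("variance", reg, reg)
        _observed_block(spec, inds)
    spec.latent.append("mtl")
    for reg in ("hippocampus", "parahippocampus"):
        spec.add("loading", reg, "mtl", free=False, value=1.0)
    for g, suff in _each_group(spec):
        spec.add("variance", "mtl", "mtl", group=g,
                 label=_glabel("var.mtl", g, suff))
        for nf in [lv for lv in spec.latent if lv.endswith("_multi")]:
            spec.add("covariance", "mtl", nf, group=g,
                     label=_glabel(f"cov.mtl.{nf}", g, suff))
    return "mtl"


# -- longitudinal stability model ---------------------------------------------


def build_stability_model(
    region: str,
    design: StudyDesign | None = None,
    groups: tuple[str, ...] | None = None,
    multimodal: bool = False,
    correlated_residuals: bool = True,
    modalities: tuple[str, ...] | None = None,
) -> ModelSpec:
    """Modality factors at TP1 and TP2 with cross-time covariances.

    ``multimodal=True`` adds a second-order integrity factor per
    timepoint whose cross-time covariance (label ``stab.<region>.multi``)
    is the error-free stability estimate; modality-specific residual
    stabilities stay in the model as first-order residual covariances.
    """
    design = design or StudyDesign()
    design.validate()
    groups = tuple(groups) if groups else ("all",)
    tps = (1, 2)
    mods_by_tp = {
        tp: tuple(modalities) if modalities else design.region_modalities(region, tp)
        for tp in tps
    }
    shared_mods = tuple(m for m in mods_by_tp[1] if m in mods_by_tp[2])
    if not shared_mods:
        raise DesignError(f"no modality observed at both timepoints for {region!r}")
    spec = ModelSpec(observed=[], latent=[], groups=list(groups))
    factors: dict[tuple[str, int], str] = {}
    for tp in tps:
        for mod in mods_by_tp[tp]:
            lv = f"{region}_{mod}_tp{tp}"
            factors[(mod, tp)] = lv
            spec.latent.append(lv)
            inds = [neural_indicator(region, mod, h, tp) for h in ("left", "right")]
            spec.observed += inds
            _measurement_block(spec, lv, inds)
            spec.add("variance", lv, lv)
            _observed_block(spec, inds)
    if correlated_residuals:
        for mod in shared_mods:
            for h in ("left", "right"):
                spec.add(
                    "covariance",
                    neural_indicator(region, mod, h, 1),
                    neural_indicator(region, mod, h, 2),
                )
    multi = len(groups) > 1
    if not multimodal:
        names = list(factors.values())
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                label = None
                for mod in shared_mods:
                    if {a, b} == {factors[(mod, 1)], factors[(mod, 2)]}:
                        label = f"stab.{region}.{mod}"
                for g, suff in _each_group(spec):
                    spec.add("covariance", a, b, group=g,
                             label=_glabel(label, g, suff) if label else None)
    else:
        tops = {}
        for tp in tps:
            top = f"{region}_multi_tp{tp}"
            tops[tp] = top
            spec.latent.append(top)
            first_order = [factors[(m, tp)] for m in mods_by_tp[tp]]
            fix_all = len(first_order) == 2
            for i, lv in enumerate(first_order):
                if i == 0 or fix_all:
                    spec.add("loading", lv, top, free=False, value=1.0)
                else:
                    for g, suff in _each_group(spec):
                        spec.add("loading", lv, top, group=g,
                                 label=_glabel(f"load.{top}.{lv}", g, suff))
            for g, suff in _each_group(spec):
                spec.add("variance", top, top, group=g,
                         label=_glabel(f"var.{top}", g, suff))
        for g, suff in _each_group(spec):
            spec.add("covariance", tops[1], tops[2], group=g,
                     label=_glabel(f"stab.{region}.multi", g, suff))
        # modality-specific residual stability
        for mod in shared_mods:
            for g, suff in _each_group(spec):
                spec.add("covariance", factors[(mod, 1)], factors[(mod, 2)],
                         group=g,
                         label=_glabel(f"rstab.{region}.{mod}", g, suff))
    spec.validate()
    return spec


# -- latent change score models -----------------------------------------------


def build_latent_change_model(
    units: list[str] | str,
    design: StudyDesign | None = None,
    groups: tuple[str, ...] | None = None,
    timepoints: tuple[int, int] = (1, 2),
    higher_order_slope: bool = False,
) -> ModelSpec:
    """Two-occasion latent change score model per unit.

    A unit is one hemisphere-averaged region-modality series or one
    cognitive task; its observed scores are ``<unit>_tp<t>``.  The base
    latent loads on both occasions, the change latent on the later one.
    Occasion residuals are fixed to 0 (observed-score change), which is
    the only identified choice with a single indicator per occasion; the
    model is then an exact reparameterisation of the occasion moments.
    """
    if isinstance(units, str):
        units = [units]
    if len(timepoints) != 2:
        raise DesignError("latent change needs exactly two timepoints")
    t1, t2 = timepoints
    groups = tuple(groups) if groups else ("all",)
    spec = ModelSpec(observed=[], latent=[], groups=list(groups))
    for u in units:
        y1, y2 = f"{u}_tp{t1}", f"{u}_tp{t2}"
        base, chg = f"{u}_base", f"{u}_chg"
        spec.observed += [y1, y2]
        spec.latent += [base, chg]
        spec.add("loading", y1, base, free=False, value=1.0)
        spec.add("loading", y2, base, free=False, value=1.0)
        spec.add("loading", y2, chg, free=False, value=1.0)
        spec.add("variance", y1, y1, free=False, value=0.0)
        spec.add("variance", y2, y2, free=False, value=0.0)
        spec.add("mean", y1, free=False, value=0.0)
        spec.add("mean", y2, free=False, value=0.0)
        for g, suff in _each_group(spec):
            spec.add("variance", base, base, group=g,
                     label=_glabel(f"base_var.{u}", g, suff))
            spec.add("mean", base, group=g,
                     label=_glabel(f"base_mean.{u}", g, suff))
            spec.add("variance", chg, chg, group=g,
                     label=_glabel(f"chg_var.{u}", g, suff))
            spec.add("mean", chg, group=g,
                     label=_glabel(f"chg_mean.{u}", g, suff))
            spec.add("covariance", base, chg, group=g,
                     label=_glabel(f"cov_base_chg.{u}", g, suff))
    if len(units) > 1:
        for i, a in enumerate(units):
            for b in units[i + 1:]:
                for g, suff in _each_group(spec):
                    spec.add("covariance", f"{a}_base", f"{b}_base", group=g,
                             label=_glabel(f"base_cov.{a}.{b}", g, suff))
                    if not higher_order_slope:
                        spec.add("covariance", f"{a}_chg", f"{b}_chg", group=g,
                                 label=_glabel(f"chg_cov.{a}.{b}", g, suff))
                    spec.add("covariance", f"{a}_base", f"{b}_chg", group=g)
                    spec.add("covariance", f"{a}_chg", f"{b}_base", group=g)
    if higher_order_slope:
        if len(units) < 2:
            raise DesignError("higher-order slope factor needs >= 2 units")
        spec.latent.append("chg_multi")
        fix_all = len(units) == 2
        for i, u in enumerate(units):
            if i == 0 or fix_all:
                spec.add("loading", f"{u}_chg", "chg_multi", free=False, value=1.0)
            else:
                for g, suff in _each_group(spec):
                    spec.add("loading", f"{u}_chg", "chg_multi", group=g,
                             label=_glabel(f"load.chg_multi.{u}", g, suff))
        for g, suff in _each_group(spec):
            spec.add("variance", "chg_multi", "chg_multi", group=g,
                     label=_glabel("chg_multi_var", g, suff))
    spec.validate()
    return spec


# -- longitudinal prediction model --------------------------------------------


def build_prediction_model(
    region: str,
    domain: str,
    design: StudyDesign | None = None,
    cognition_tp: int = 3,
) -> ModelSpec:
    """Multimodal neural change (TP1-TP2) and age predicting future cognition.

    Single-group (older adults only).  Age regresses on the multimodal
    change factor (label ``beta.chg_multi.age``) and, jointly with the
    change factor, on the TP<cognition_tp> cognitive factor (labels
    ``beta.<domain>.chg_multi`` and ``beta.<domain>.age``).
    """
    design = design or StudyDesign()
    design.validate()
    if domain not in design.task_map:
        raise DesignError(f"unknown cognitive domain {domain!r}")
    mods = tuple(m for m in design.region_modalities(region, 1)
                 if m in design.region_modalities(region, 2))
    units = [neural_avg_indicator(region, m, 0).replace("_tp0", "") for m in mods]
    spec = build_latent_change_model(units, design, higher_order_slope=True)
    # age: observed exogenous predictor
    spec.observed.append("age")
    spec.add("variance", "age", "age")
    spec.add("mean", "age")
    for u in units:
        spec.add("covariance", "age", f"{u}_base")
    spec.add("regression", "chg_multi", "age", label="beta.chg_multi.age")
    # future cognition measurement block
    inds = [cognitive_indicator(t, cognition_tp) for t in design.task_map[domain]]
    spec.observed += inds
    spec.latent.append(domain)
    _measurement_block(spec, domain, inds)
    spec.add("variance", domain, domain)
    _observed_block(spec, inds)
    spec.add("regression", domain, "chg_multi", label=f"beta.{domain}.chg_multi")
    spec.add("regression", domain, "age", label=f"beta.{domain}.age")
    # baseline neural level may relate to later cognition
    for u in units:
        spec.add("covariance", domain, f"{u}_base")
    spec.validate()
    return spec
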