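"""Fixed study design: regions, modalities, task map, groups, timepoints."""

from __future__ import annotations

from dataclasses import dataclass, field


class DesignError(ValueError):
    pass


TASK_MAP: dict[str, tuple[str, ...]] = {
    "wm": ("spatial_u", "letter_u", "number"),
    "em": ("scene", "list", "face", "object"),
    "gf": ("problem", "analog", "letter"),
}


def _default_modalities() -> dict[str, dict[int, tuple[str, ...]]]:
    # FSE covers the brainstem only (no SN-VTA) and exists at TP2 only.
    return {
        "lc": {1: ("mtplus", "mtminus"), 2: ("mtplus", "mtminus", "fse")},
        "snvta": {1: ("mtplus", "mtminus"), 2: ("mtplus", "mtminus")},
    }


@dataclass
class StudyDesign:
    regions: tuple[str, ...] = ("lc", "snvta")
    modalities: dict[str, dict[int, tuple[str, ...]]] = field(
        default_factory=_default_modalities
    )
    task_map: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(TASK_MAP)
    )
    groups: tuple[str, ...] = ("younger", "older")
    timepoints: tuple[int, ...] = (1, 2, 3)

    def validate(self) -> None:
        tasks = [t for ts in self.task_map.values() for t in ts]
        if len(tasks) != len(set(tasks)):
            raise DesignError("task map assigns a task to more than one factor")
        if len(tasks) != 10:
            raise DesignError(f"task map must partition 10 tasks, has {len(tasks)}")
        for region, by_tp in self.modalities.items():
            for tp, mods in by_tp.items():
                if region == "snvta" and "fse" in mods:
                    raise DesignError("FSE cannot be paired with SN-VTA")
                if tp == 1 and "fse" in mods:
                    raise DesignError("FSE is not acquired at TP1")

    def region_modalities(self, region: str, timepoint: int) -> tuple[str, ...]:
        if region not in self.modalities:
            raise DesignError(f"unknown region {region!r}")
        mods = self.modalities[region].get(timepoint, ())
        if not mods:
            raise DesignError(f"no modalities for {region!r} at TP{timepoint}")
        return mods

    @property
    def tasks(self) -> tuple[str, ...]:
        return tuple(t for ts in self.task_map.values() for t in ts)


def neural_indicator(region: str, modality: str, hemisphere: str, tp: int) -> str:
    return f"{region}_{modality}_{hemisphere}_tp{tp}"


def neural_avg_indicator(region: str, modality: str, tp: int) -> str:
    return f"{region}_{modality}_tp{tp}"


def cognitive_indicator(task: str, tp: int) -> str:
    return f"{task}_tp{tp}"
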