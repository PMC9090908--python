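"""Decision-rule models for defense systems and the profile manifest.

A defense system model describes the genetic architecture of one (sub)type:
which protein components it is made of, which of them are mandatory,
accessory or forbidden, which profiles are accepted as interchangeable
evidence for each component, and the quorum (minimum numbers of mandatory and
total components) plus the co-localization window the detection engine
applies.  Models are data, not code: the same engine runs every system.

The registry is a directory::

    registry/
      models/*.yaml      one model document per (sub)type
      profiles.tsv       manifest: profile_name, GA_bits, source
      profiles/*.prf     profile parameters (optional when hits are precomputed)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

ROLES = ("mandatory", "accessory", "forbidden", "neutral")
MECHANISMS = (
    "nucleic-acid degradation",
    "abortive infection",
    "inhibition of DNA/RNA synthesis",
    "unknown",
)


@dataclass
class ComponentDef:
    name: str
    role: str
    profiles: tuple[str, ...]

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"component {self.name}: unknown role {self.role!r}")
        if not self.profiles:
            raise ValueError(f"component {self.name}: profiles must be non-empty")
        self.profiles = tuple(self.profiles)


@dataclass
class SystemModel:
    """Decision rule for one defense system (sub)type."""

    model_name: str
    family: str
    subtype: str
    components: list[ComponentDef]
    min_mandatory: int | None = None
    min_total: int | None = None
    window_W: int = 5
    multi_loci: bool = False
    mechanism: str = "unknown"

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(
                f"model {self.model_name}: unknown mechanism {self.mechanism!r}"
            )
        n_mandatory = sum(1 for c in self.components if c.role == "mandatory")
        # conservative full-system defaults: all mandatory components required
        if self.min_mandatory is None:
            self.min_mandatory = n_mandatory
        if self.min_total is None:
            self.min_total = self.min_mandatory
        if self.min_mandatory > n_mandatory:
            raise ValueError(
                f"model {self.model_name}: min_mandatory {self.min_mandatory} exceeds "
                f"number of mandatory components ({n_mandatory})"
            )
        if self.min_total < self.min_mandatory:
            raise ValueError(
                f"model {self.model_name}: min_total < min_mandatory"
            )
        if self.window_W < 0:
            raise ValueError(f"model {self.model_name}: window_W must be >= 0")

    @property
    def mandatory_components(self) -> list[ComponentDef]:
        return [c for c in self.components if c.role == "mandatory"]

    @property
    def forbidden_profiles(self) -> set[str]:
        return {p for c in self.components if c.role == "forbidden" for p in c.profiles}

    @property
    def detection_profiles(self) -> set[str]:
        """Profiles evidencing non-forbidden components."""
        return {p for c in self.components if c.role != "forbidden" for p in c.profiles}


@dataclass
class Registry:
    """Validated collection of system models plus the profile manifest.

    ``profile_manifest`` maps profile_name to ``{"GA_bits": float,
    "source": "packaged"|"toy"}``.  ``profiles`` optionally holds loaded
    ProfileHMM objects keyed by name (required for internal scanning,
    not for precomputed-hit ingestion).
    """

    models: list[SystemModel] = field(default_factory=list)
    profile_manifest: dict[str, dict] = field(default_factory=dict)
    profiles: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        names = [m.model_name for m in self.models]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate model_name(s): {dup}")
        pairs = [(m.family, m.subtype) for m in self.models]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (family, subtype) pair in registry")
        for m in self.models:
            for c in m.components:
                for p in c.profiles:
                    if p not in self.profile_manifest:
                        raise ValueError(
                            f"model {m.model_name}: profile {p!r} absent from manifest"
                        )
        for p, entry in self.profile_manifest.items():
            ga = entry.get("GA_bits")
            if ga is None or not math.isfinite(float(ga)):
                raise ValueError(f"profile {p}: GA_bits must be finite")

    def ga_bits(self, profile_name: str) -> float:
        return float(self.profile_manifest[profile_name]["GA_bits"])

    def get_model(self, model_name: str) -> SystemModel:
        for m in self.models:
            if m.model_name == model_name:
                return m
        raise KeyError(model_name)

    def annotate_ga(self, hits) -> list:
        """Set each hit's ga_pass flag from the manifest (score >= GA)."""
        out = []
        for h in hits:
            if h.profile_name in self.profile_manifest:
                h.ga_pass = h.score_bits >= self.ga_bits(h.profile_name)
            out.append(h)
        return out


def _model_from_dict(doc: dict, origin: str) -> SystemModel:
    try:
        quorum = doc.get("quorum", {}) or {}
        components = [
            ComponentDef(c["name"], c["role"], tuple(c["profiles"]))
            for c in doc["components"]
        ]
        return SystemModel(
            model_name=doc["model_name"],
            family=doc["family"],
            subtype=doc["subtype"],
            components=components,
            min_mandatory=quorum.get("min_mandatory"),
            min_total=quorum.get("min_total"),
            window_W=int(quorum.get("window_W", 5)),
            multi_loci=bool(quorum.get("multi_loci", False)),
            mechanism=doc.get("mechanism", "unknown"),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"{origin}: invalid model document: {exc}") from None


def load_registry(path: str | Path, load_profiles: bool = True) -> Registry:
    """Load and validate a registry directory.

    Model files are read in sorted order so the result is independent of
    filesystem ordering.  Errors name the offending file.
    """
    path = Path(path)
    manifest_path = path / "profiles.tsv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"registry {path}: missing profiles.tsv manifest")
    manifest_df = pd.read_csv(manifest_path, sep="\t")
    for col in ("profile_name", "GA_bits", "source"):
        if col not in manifest_df.columns:
            raise ValueError(f"{manifest_path}: missing manifest column {col!r}")
    manifest = {
        str(r.profile_name): {"GA_bits": float(r.GA_bits), "source": str(r.source)}
        for r in manifest_df.itertuples()
    }

    models = []
    models_dir = path / "models"
    if models_dir.is_dir():
        for f in sorted(models_dir.glob("*.yaml")):
            with open(f) as fh:
                doc = yaml.safe_load(fh)
            models.append(_model_from_dict(doc, str(f)))

    profiles = {}
    profiles_dir = path / "profiles"
    if load_profiles and profiles_dir.is_dir():
        from .profile_hmm import read_profile
        for f in sorted(profiles_dir.glob("*.prf")):
            prof = read_profile(f)
            profiles[prof.profile_name] = prof

    try:
        return Registry(models, manifest, profiles)
    except ValueError as exc:
        raise ValueError(f"registry {path}: {exc}") from None


def write_registry(registry: Registry, path: str | Path) -> None:
    """Serialize a registry to a directory (inverse of load_registry)."""
    path = Path(path)
    (path / "models").mkdir(parents=True, exist_ok=True)
    for m in registry.models:
        doc = {
            "model_name": m.model_name,
            "family": m.family,
            "subtype": m.subtype,
            "mechanism": m.mechanism,
            "quorum": {
                "min_mandatory": m.min_mandatory,
                "min_total": m.min_total,
                "window_W": m.window_W,
                "multi_loci": m.multi_loci,
            },
            "components": [
                {"name": c.name, "role": c.role, "profiles": list(c.profiles)}
                for c in m.components
            ],
        }
        with open(path / "models" / f"{m.model_name}.yaml", "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
    rows = [
        {"profile_name": p, "GA_bits": e["GA_bits"], "source": e["source"]}
        for p, e in sorted(registry.profile_manifest.items())
    ]
    pd.DataFrame(rows, columns=["profile_name", "GA_bits", "source"]).to_csv(
        path / "profiles.tsv", sep="\t", index=False
    )
    if registry.profiles:
        from .profile_hmm import write_profile
        (path / "profiles").mkdir(exist_ok=True)
        for name, prof in sorted(registry.profiles.items()):
            write_profile(prof, path / "profiles" / f"{name}.prf")


def registry_stats(registry: Registry) -> dict:
    """Catalog summary: families, (sub)types, profiles, subtypes per family."""
    families = sorted({m.family for m in registry.models})
    by_family: dict[str, int] = {}
    for m in registry.models:
        by_family[m.family] = by_family.get(m.family, 0) + 1
    return {
        "n_families": len(families),
        "n_subtypes": len(registry.models),
        "n_profiles": len(registry.profile_manifest),
        "n_subtypes_by_family": by_family,
    }


def mechanism_breakdown(calls, registry: Registry) -> dict[str, float]:
    """Fraction of calls per antiviral mechanism category.

    Fractions are over all calls and sum to 1; an empty call list yields an
    empty map.
    """
    if not calls:
        return {}
    counts: dict[str, int] = {}
    for call in calls:
        model = registry.get_model(call.model_name)  # KeyError on unknown model
        counts[model.mechanism] = counts.get(model.mechanism, 0) + 1
    n = len(calls)
    return {mech: c / n for mech, c in sorted(counts.items())}
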