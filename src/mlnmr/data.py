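"""Data model and I/O for treatment networks mixing individual and aggregate data.

Individual patient data (IPD) studies carry one record per randomized
participant; aggregate data (AgD) studies carry one record per arm (event
count and sample size for binary outcomes, mean and standard error for
continuous ones) together with study-level marginal covariate summaries.
A :class:`Network` ties the studies together and checks that the implied
graph of treatment comparisons is connected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """A required column is absent or the column mapping is inconsistent."""


class ValidationError(ValueError):
    """Data content violates an invariant (ranges, types, completeness)."""


@dataclass(frozen=True)
class Treatment:
    """A treatment node in the network.

    ``class_id`` groups treatments into mutually exclusive classes for
    shared or exchangeable effect-modifier structures.  Exactly one
    treatment in a network is the reference.
    """

    id: str
    class_id: str | None = None
    is_reference: bool = False


@dataclass(frozen=True)
class IPDSchema:
    study: str = "study"
    treatment: str = "treatment"
    outcome: str = "y"
    covariates: tuple[str, ...] = ()


@dataclass(frozen=True)
class AgDSchema:
    study: str = "study"
    treatment: str = "treatment"
    events: str = "events"
    sample_size: str = "n"
    mean: str = "mean"
    se: str = "se"
    covariates: tuple[str, ...] = ()


@dataclass
class IPDStudy:
    """One randomized trial with individual records.

    ``data`` has columns ``treatment``, ``y`` and one column per covariate.
    """

    study_id: str
    data: pd.DataFrame
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        required = {"treatment", "y", *self.covariates}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(
                f"IPD study {self.study_id!r}: missing columns {sorted(missing)}"
            )
        if len(self.data) == 0:
            raise ValidationError(f"IPD study {self.study_id!r} has no rows")
        for cov in self.covariates:
            if self.data[cov].isna().any():
                row = int(self.data[cov].isna().idxmax())
                raise ValidationError(
                    f"IPD study {self.study_id!r}: missing value for covariate "
                    f"{cov!r} at row {row}"
                )
        if self.data["y"].isna().any():
            raise ValidationError(f"IPD study {self.study_id!r}: missing outcome values")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def treatments(self) -> list[str]:
        return list(pd.unique(self.data["treatment"]))

    def validate_binary(self) -> None:
        y = self.data["y"].to_numpy()
        if not np.isin(y, [0, 1]).all():
            bad = np.flatnonzero(~np.isin(y, [0, 1]))[0]
            raise ValidationError(
                f"IPD study {self.study_id!r}: non-binary outcome at row {int(bad)}"
            )


@dataclass
class AgDStudy:
    """One trial known only through published arm-level summaries.

    ``arms`` has columns ``treatment``, ``y`` (event count or mean), ``n``
    (randomized sample size) and, for continuous outcomes, ``se``.
    ``covariate_summaries`` maps covariate name to a dict with keys drawn
    from ``{"mean", "sd", "prop"}`` describing the study-level marginal.
    """

    study_id: str
    arms: pd.DataFrame
    covariate_summaries: dict[str, dict[str, float]] = field(default_factory=dict)
    outcome: str = "binary"

    def __post_init__(self) -> None:
        required = {"treatment", "y", "n"}
        missing = required - set(self.arms.columns)
        if missing:
            raise SchemaError(
                f"AgD study {self.study_id!r}: missing columns {sorted(missing)}"
            )
        if (self.arms["n"] <= 0).any():
            raise ValidationError(f"AgD study {self.study_id!r}: non-positive sample size")
        if self.arms["treatment"].duplicated().any():
            dupes = self.arms["treatment"][self.arms["treatment"].duplicated()].tolist()
            warnings.warn(
                f"AgD study {self.study_id!r}: merging duplicate arms for {dupes}",
                stacklevel=2,
            )
            self.arms = (
                self.arms.groupby("treatment", as_index=False, sort=False)
                .agg({c: "sum" for c in self.arms.columns if c != "treatment"})
            )
        if self.outcome == "binary":
            y, n = self.arms["y"].to_numpy(), self.arms["n"].to_numpy()
            if not (np.equal(np.mod(y, 1), 0).all() and np.equal(np.mod(n, 1), 0).all()):
                raise ValidationError(
                    f"AgD study {self.study_id!r}: binary outcome requires integer "
                    "event counts and sample sizes"
                )
            if ((y < 0) | (y > n)).any():
                raise ValidationError(
                    f"AgD study {self.study_id!r}: event count outside [0, N]"
                )
        for name, summ in self.covariate_summaries.items():
            prop = summ.get("prop")
            if prop is not None and not (0.0 <= prop <= 1.0):
                raise ValidationError(
                    f"AgD study {self.study_id!r}: proportion for {name!r} is {prop}, "
                    "outside [0, 1]"
                )
        if len(self.arms) == 1:
            warnings.warn(
                f"AgD study {self.study_id!r} has a single arm; it is accepted as "
                "data but excluded from relative-effect estimation by default",
                stacklevel=2,
            )

    @property
    def treatments(self) -> list[str]:
        return list(self.arms["treatment"])

    @property
    def n_total(self) -> int:
        return int(self.arms["n"].sum())


Study = IPDStudy | AgDStudy


def _as_frame(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source)


def read_ipd(source, schema: IPDSchema) -> list[IPDStudy]:
    """Read a long-format IPD table (one row per individual) into studies.

    Parameters
    ----------
    source : path, file-like or DataFrame
        CSV source with columns named in ``schema``.
    schema : IPDSchema
        Column mapping, including the covariate column names.
    """
    df = _as_frame(source)
    needed = [schema.study, schema.treatment, schema.outcome, *schema.covariates]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"IPD table is missing columns {missing}")
    if len(df) == 0:
        raise ValidationError("IPD table has no rows")
    rename = {schema.treatment: "treatment", schema.outcome: "y"}
    studies = []
    for study_id, block in df.groupby(schema.study, sort=False):
        data = block.rename(columns=rename)[["treatment", "y", *schema.covariates]]
        data = data.reset_index(drop=True)
        data["treatment"] = data["treatment"].astype(str)
        studies.append(IPDStudy(str(study_id), data, tuple(schema.covariates)))
    return studies


def write_ipd(studies: Sequence[IPDStudy], schema: IPDSchema, path=None):
    """Inverse of :func:`read_ipd`; returns the DataFrame, optionally writing CSV."""
    frames = []
    for s in studies:
        block = s.data.rename(columns={"treatment": schema.treatment, "y": schema.outcome})
        block.insert(0, schema.study, s.study_id)
        frames.append(block)
    out = pd.concat(frames, ignore_index=True)
    if path is not None:
        out.to_csv(path, index=False)
    return out


def read_agd(source, schema: AgDSchema, outcome: str = "binary") -> list[AgDStudy]:
    """Read an arm-level AgD table into studies.

    The table has one row per arm.  Binary outcomes use the ``events`` and
    ``sample_size`` columns; continuous outcomes use ``mean``, ``se`` and
    ``sample_size``.  Study-level covariate summaries ride along as wide
    columns ``cov_<name>_mean``, ``cov_<name>_sd`` and ``cov_<name>_prop``
    (constant within a study).
    """
    df = _as_frame(source)
    if outcome == "binary":
        needed = [schema.study, schema.treatment, schema.events, schema.sample_size]
    else:
        needed = [schema.study, schema.treatment, schema.mean, schema.se, schema.sample_size]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"AgD table is missing columns {missing}")

    studies = []
    for study_id, block in df.groupby(schema.study, sort=False):
        if outcome == "binary":
            arms = pd.DataFrame(
                {
                    "treatment": block[schema.treatment].astype(str),
                    "y": block[schema.events].to_numpy(),
                    "n": block[schema.sample_size].to_numpy(),
                }
            )
        else:
            arms = pd.DataFrame(
                {
                    "treatment": block[schema.treatment].astype(str),
                    "y": block[schema.mean].to_numpy(),
                    "se": block[schema.se].to_numpy(),
                    "n": block[schema.sample_size].to_numpy(),
                }
            )
        summaries: dict[str, dict[str, float]] = {}
        for name in schema.covariates:
            entry = {}
            for stat in ("mean", "sd", "prop"):
                col = f"cov_{name}_{stat}"
                if col in block.columns:
                    val = block[col].iloc[0]
                    if pd.notna(val):
                        entry[stat] = float(val)
            if not entry:
                raise ValidationError(
                    f"AgD study {study_id!r}: no covariate summary for declared "
                    f"covariate {name!r}"
                )
            summaries[name] = entry
        arms = arms.reset_index(drop=True)
        studies.append(AgDStudy(str(study_id), arms, summaries, outcome=outcome))
    return studies


@dataclass
class Network:
    """A connected network of treatment comparisons over mixed studies.

    The reference treatment is stored first; integer coding of treatments
    and studies is internal and never appears in outputs.
    """

    treatments: list[Treatment]
    studies: list[Study]
    covariates: tuple[str, ...] = ()
    outcome: str = "binary"

    def __post_init__(self) -> None:
        refs = [t for t in self.treatments if t.is_reference]
        if len(refs) != 1:
            raise ValidationError(
                f"network must have exactly one reference treatment, found {len(refs)}"
            )
        # reference first; everything else keeps its given order
        self.treatments = refs + [t for t in self.treatments if not t.is_reference]
        self._index = {t.id: i for i, t in enumerate(self.treatments)}
        if len(self._index) != len(self.treatments):
            raise ValidationError("duplicate treatment ids")

    @property
    def reference(self) -> Treatment:
        return self.treatments[0]

    @property
    def K(self) -> int:
        return len(self.treatments)

    def treatment_index(self, treatment_id: str) -> int:
        try:
            return self._index[treatment_id]
        except KeyError:
            raise KeyError(f"treatment {treatment_id!r} is not in the network") from None

    @property
    def ipd_studies(self) -> list[IPDStudy]:
        return [s for s in self.studies if isinstance(s, IPDStudy)]

    @property
    def agd_studies(self) -> list[AgDStudy]:
        return [s for s in self.studies if isinstance(s, AgDStudy)]

    @property
    def fit_studies(self) -> list[Study]:
        """Studies contributing to relative-effect estimation (≥2 arms)."""
        return [s for s in self.studies if len(set(s.treatments)) >= 2]

    def classes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for t in self.treatments:
            if t.class_id is not None:
                out.setdefault(t.class_id, []).append(t.id)
        return out


def connectivity_components(studies: Sequence[Study]) -> list[set[str]]:
    """Connected components of the graph whose edges are within-study pairs."""
    g = nx.Graph()
    for s in studies:
        trts = list(dict.fromkeys(s.treatments))
        g.add_nodes_from(trts)
        for a, b in zip(trts, trts[1:]):
            g.add_edge(a, b)
    return [set(c) for c in nx.connected_components(g)]


def build_network(
    studies: Sequence[Study],
    reference: str,
    treatment_classes: Mapping[str, Iterable[str]] | None = None,
    covariates: Sequence[str] = (),
    outcome: str = "binary",
) -> Network:
    """Assemble and validate a :class:`Network`.

    Raises
    ------
    ValidationError
        If the treatment graph is disconnected (the components are listed),
        or a declared covariate is absent from some study.
    """
    if len(studies) == 0:
        raise ValidationError("at least one study is required")
    components = connectivity_components(studies)
    if len(components) > 1:
        raise ValidationError(
            "treatment network is disconnected; components: "
            + "; ".join(sorted(",".join(sorted(c)) for c in components))
        )
    all_treatments = sorted({t for s in studies for t in s.treatments})
    if reference not in all_treatments:
        raise ValidationError(f"reference treatment {reference!r} appears in no study")

    class_of: dict[str, str] = {}
    if treatment_classes:
        for cls, members in treatment_classes.items():
            for m in members:
                if m in class_of:
                    raise ValidationError(
                        f"treatment {m!r} assigned to both classes "
                        f"{class_of[m]!r} and {cls!r}"
                    )
                class_of[m] = cls

    treatments = [
        Treatment(t, class_id=class_of.get(t), is_reference=(t == reference))
        for t in all_treatments
    ]

    for s in studies:
        if isinstance(s, IPDStudy):
            missing = [c for c in covariates if c not in s.data.columns]
            if missing:
                raise ValidationError(
                    f"IPD study {s.study_id!r} lacks covariates {missing}"
                )
            if outcome == "binary":
                s.validate_binary()
        else:
            missing = [c for c in covariates if c not in s.covariate_summaries]
            if missing:
                raise ValidationError(
                    f"AgD study {s.study_id!r} lacks covariate summaries for {missing}"
                )

    return Network(treatments, list(studies), tuple(covariates), outcome)
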