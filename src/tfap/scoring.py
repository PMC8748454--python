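"""Drugs x TFs activation matrix, panel filtering and drug ranking.

The screen's end product is a matrix of signed TF activation states — one
row per drug, one column per TF — reduced to a panel of TFs that drive the
phenotype of interest (here, myeloid differentiation) and collapsed per
drug into an integer pro-differentiation score:

    score = #(panel TFs activated) - #(panel TFs repressed).

Unchanged and excluded (both-lists) TFs contribute nothing.  Drugs are
ranked by descending score with a deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import ACTIVATED, EXCLUDED, REPRESSED, UNCHANGED

_VALID_STATES = frozenset({ACTIVATED, REPRESSED, UNCHANGED, EXCLUDED})


@dataclass(frozen=True)
class TFPanel:
    """Ordered set of phenotype-relevant TFs (e.g. myeloid master regulators)."""

    tf_ids: tuple
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.tf_ids:
            raise ValueError("TF panel must not be empty")
        if len(set(self.tf_ids)) != len(self.tf_ids):
            raise ValueError("TF panel contains duplicates")

    @classmethod
    def from_file(cls, path, provenance: str | None = None) -> "TFPanel":
        """One TF id per line; blank lines and '#' comments ignored."""
        ids = []
        for line in open(path):
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line.upper())
        return cls(tf_ids=tuple(ids), provenance=provenance or str(path))


@dataclass
class ActivationMatrix:
    """Dense drugs x TFs matrix of states in {+1, -1, 0, EXCLUDED}."""

    states: pd.DataFrame  # index: drug ids; columns: tf ids; dtype int8

    def __post_init__(self) -> None:
        bad = set(np.unique(self.states.to_numpy())) - _VALID_STATES
        if bad:
            raise ValueError(f"invalid activation states {sorted(bad)}")
        self.states = self.states.astype(np.int8)

    @property
    def drugs(self) -> list[str]:
        return list(self.states.index)

    @property
    def tfs(self) -> list[str]:
        return list(self.states.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.states.shape


def build_activation_matrix(per_drug_states: dict) -> ActivationMatrix:
    """Assemble per-drug state mappings into one dense matrix.

    ``per_drug_states`` maps drug id -> {tf id -> state}.  Every drug must
    cover the identical TF union; row order follows insertion order of the
    input, column order the first drug's TF ids sorted.
    """
    drugs = list(per_drug_states)
    if not drugs:
        return ActivationMatrix(
            states=pd.DataFrame(dtype=np.int8, index=pd.Index([], name="drug_id"))
        )
    tf_axis = sorted(per_drug_states[drugs[0]])
    ref = set(tf_axis)
    rows = []
    for drug in drugs:
        states = per_drug_states[drug]
        if set(states) != ref:
            raise ValueError(
                f"drug {drug!r} covers a different TF set than {drugs[0]!r}"
            )
        rows.append([states[tf] for tf in tf_axis])
    df = pd.DataFrame(
        rows,
        index=pd.Index(drugs, name="drug_id"),
        columns=tf_axis,
        dtype=np.int8,
    )
    return ActivationMatrix(states=df)


def filter_to_panel(
    matrix: ActivationMatrix, panel: TFPanel, drop_inert: bool = True
) -> tuple[ActivationMatrix, list]:
    """Restrict columns to the panel; optionally drop drugs inert on it.

    A drug "has an effect" on the panel when at least one panel state is
    +1 or -1 (excluded cells are not an effect).  Returns the reduced
    matrix and the list of panel TFs missing from the matrix.
    """
    present = [tf for tf in panel.tf_ids if tf in matrix.states.columns]
    missing = [tf for tf in panel.tf_ids if tf not in matrix.states.columns]
    if not present:
        raise ValueError("panel does not intersect the matrix's TF axis")
    sub = matrix.states[present]
    if drop_inert:
        active = ((sub == ACTIVATED) | (sub == REPRESSED)).any(axis=1)
        sub = sub.loc[active]
    return ActivationMatrix(states=sub.copy()), missing


def prodiff_score(row) -> int:
    """#activated - #repressed over a panel row of states."""
    arr = np.asarray(row)
    return int((arr == ACTIVATED).sum() - (arr == REPRESSED).sum())


def rank_drugs(matrix: ActivationMatrix, panel: TFPanel | None = None) -> pd.DataFrame:
    """Rank drugs by descending pro-differentiation score.

    Ties break by larger number of activated TFs, then lexicographic drug
    id.  Returns a DataFrame with columns ``drug_id``, ``score``,
    ``n_activated``, ``n_inhibited`` in rank order.
    """
    if panel is not None:
        matrix, _ = filter_to_panel(matrix, panel, drop_inert=False)
    arr = matrix.states.to_numpy()
    n_act = (arr == ACTIVATED).sum(axis=1)
    n_inh = (arr == REPRESSED).sum(axis=1)
    df = pd.DataFrame(
        {
            "drug_id": matrix.drugs,
            "score": n_act - n_inh,
            "n_activated": n_act,
            "n_inhibited": n_inh,
        }
    )
    df = df.sort_values(
        by=["score", "n_activated", "drug_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


# -- serialization -------------------------------------------------------------

_STATE_TO_TEXT = {ACTIVATED: "1", REPRESSED: "-1", UNCHANGED: "0", EXCLUDED: "NA"}
_TEXT_TO_STATE = {v: k for k, v in _STATE_TO_TEXT.items()}


def write_activation_matrix(matrix: ActivationMatrix, path) -> None:
    """TSV with states encoded {1, -1, 0, NA} (NA = excluded)."""
    with open(path, "w") as fh:
        fh.write("drug_id\t" + "\t".join(matrix.tfs) + "\n")
        for drug, row in matrix.states.iterrows():
            cells = "\t".join(_STATE_TO_TEXT[int(v)] for v in row)
            fh.write(f"{drug}\t{cells}\n")


def read_activation_matrix(path) -> ActivationMatrix:
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    try:
        states = raw.map(lambda v: _TEXT_TO_STATE[v])
    except KeyError as exc:
        raise ValueError(f"invalid state token {exc.args[0]!r}") from None
    states.index.name = "drug_id"
    return ActivationMatrix(states=states.astype(np.int8))
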