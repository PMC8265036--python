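"""Worked-example regulatory circuits from the bacterial GRN literature.

Each fixture is a small, fully specified circuit illustrating one class in
the fiber hierarchy: a didactic two-target fan-out, the Fis and Crp/Fis
regulons, the tryptophan autorepression loop, the purine feed-forward
fiber, the OxyR/RbsR multilayer composite, and the UxuR/ExuR feedback loop
whose input-tree layers grow like a Fibonacci sequence.  Edge signs follow
the textual descriptions where stated (TrpR represses; PurR represses);
where a description is silent, activation is the default — see
``FIXTURE_NOTES``.
"""

from __future__ import annotations

from .grn import ACTIVATION, REPRESSION, RegNetwork

__all__ = ["fixtures", "FIXTURE_NAMES", "FIXTURE_NOTES"]


def _net(edges) -> RegNetwork:
    return RegNetwork.from_edges(edges)


_BUILDERS = {
    # didactic fan-out: one source driving two identical targets
    "fig1": lambda: _net([("1", "2", ACTIVATION), ("1", "3", ACTIVATION)]),
    # fis regulon (|0,1>): four targets under one TF, fis itself under crp
    "fig2a": lambda: _net(
        [("crp", "fis", ACTIVATION)]
        + [("fis", t, ACTIVATION) for t in ("cbpAM", "gltX", "gyrB", "msrA")]
    ),
    # two-regulator regulon (|0,2>, the FAN motif)
    "fig2b": lambda: _net(
        [
            (tf, t, ACTIVATION)
            for tf in ("crp", "fis")
            for t in ("clrA", "fiu", "entCEBAH", "fepA-entD")
        ]
    ),
    # tryptophan autorepression loop (|1,0>): trpR represses itself and two units
    "fig3": lambda: _net(
        [
            ("trpR", "trpR", REPRESSION),
            ("trpR", "aroH", REPRESSION),
            ("trpR", "trpLEDCBA", REPRESSION),
        ]
    ),
    # purine feed-forward fiber (|1,1>): autorepressing purR and pyrC under fur
    "fig4": lambda: _net(
        [
            ("fur", "purR", ACTIVATION),
            ("fur", "pyrC", ACTIVATION),
            ("purR", "purR", REPRESSION),
            ("purR", "pyrC", REPRESSION),
        ]
    ),
    # multilayer composite |0,1>(+)|1,1>: crp drives the {oxyR, rbsR} fiber,
    # which drives the seven-gene red fiber
    "fig5": lambda: _net(
        [
            ("crp", "oxyR", ACTIVATION),
            ("crp", "rbsR", ACTIVATION),
            ("oxyR", "oxyR", ACTIVATION),
            ("oxyR", "rbsR", ACTIVATION),
        ]
        + [
            ("oxyR", t, ACTIVATION)
            for t in ("add", "dsbG", "gor", "grxA", "hemH", "oxyS", "trxC")
        ]
    ),
    # Fibonacci feedback loop: uxuR autoregulates, drives exuR and lgoR,
    # and exuR feeds back to uxuR
    "fig6": lambda: _net(
        [
            ("uxuR", "uxuR", ACTIVATION),
            ("uxuR", "exuR", ACTIVATION),
            ("exuR", "uxuR", ACTIVATION),
            ("uxuR", "lgoR", ACTIVATION),
        ]
    ),
}

FIXTURE_NAMES = tuple(sorted(_BUILDERS))

FIXTURE_NOTES = {
    "fig1": "didactic circuit; signs not specified in the source, activation used",
    "fig2a": "regulon wiring from the caption text; activation assumed",
    "fig2b": "two-regulator regulon; activation assumed",
    "fig3": "repression edges as stated (TrpR represses itself, aroH, trpLEDCBA)",
    "fig4": "purR edges repression (PurR is a repressor); fur edges activation",
    "fig5": (
        "topology partially figure-derived: the wiring of add (reported two "
        "steps from the rest of its fiber) is simplified to a direct oxyR "
        "edge; informational only"
    ),
    "fig6": (
        "loop topology from the caption; the second external regulator is "
        "visible only in the figure, so this fixture carries l=1 and is used "
        "for the branching-ratio check"
    ),
}


def fixtures(name: str) -> RegNetwork:
    """Return a named worked-example circuit as a :class:`RegNetwork`."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}"
        ) from None
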