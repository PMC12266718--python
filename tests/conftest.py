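"""Shared helpers: graph builders and a fast engine configuration."""

from __future__ import annotations

import json

import pytest

import rigflow as rf
from rigflow.engine import EngineConfig


def make_graph_text(nodes, edges):
    return json.dumps({"schema_version": "1", "nodes": nodes, "edges": edges})


def node(base, node_type, inputs=(), outputs=(), worker_ref="", params=None, **extra):
    d = {
        "base_name": base,
        "node_type": node_type,
        "inputs": list(inputs),
        "outputs": list(outputs),
        "worker_ref": worker_ref,
        "parameters": [
            {"name": k, "value": v} if not isinstance(v, dict) else {"name": k, **v}
            for k, v in (params or {}).items()
        ],
    }
    d.update(extra)
    return d


def edge(from_node, from_output, to_node, to_input):
    return {
        "from_node": from_node,
        "from_output": from_output,
        "to_node": to_node,
        "to_input": to_input,
    }


def chain_graph(n_transforms=1, schedule=None, interval_s=0.005, sink_ref="rigflow.nodes.basic:null_sink"):
    """source -> n identity transforms -> sink."""
    schedule = list(range(20)) if schedule is None else schedule
    nodes = [
        node(
            "Src",
            "source",
            outputs=["Out"],
            worker_ref="rigflow.nodes.basic:scripted_source",
            params={"schedule": schedule, "interval_s": interval_s},
        )
    ]
    edges = []
    prev = ("Src##0", "Out")
    for i in range(n_transforms):
        nodes.append(
            node(
                f"T{i}",
                "transform",
                inputs=["In"],
                outputs=["Out"],
                worker_ref="rigflow.nodes.basic:identity_transform",
            )
        )
        edges.append(edge(prev[0], prev[1], f"T{i}##0", "In"))
        prev = (f"T{i}##0", "Out")
    nodes.append(node("Snk", "sink", inputs=["In"], worker_ref=sink_ref))
    edges.append(edge(prev[0], prev[1], "Snk##0", "In"))
    return rf.parse_graph(make_graph_text(nodes, edges))


def prl_graph_text(table_path, max_trials=40, seed_block_range=(5, 10), inter_trial_s=0.01):
    nodes = [
        node(
            "KeyPress",
            "source",
            outputs=["Key"],
            worker_ref="rigflow.nodes.basic:scripted_source",
            params={"schedule": [{"key": "start"}]},
        ),
        node(
            "Trial Generator",
            "transform",
            inputs=["Start/Previous Trial Result"],
            outputs=["Trial Definition"],
            worker_ref="rigflow.nodes.prl:trial_generator",
            params={"max_trials": max_trials, "block_length_range": list(seed_block_range)},
        ),
        node(
            "Trial Controller",
            "transform",
            inputs=["Trial Definition"],
            outputs=["Trial Result", "Trial History"],
            worker_ref="rigflow.nodes.prl:trial_controller",
            params={
                "inter_trial_s": inter_trial_s,
                "reward_only_after_lick": {"value": True, "updatable": False},
            },
        ),
        node(
            "Save Pandas DF",
            "sink",
            inputs=["Row"],
            worker_ref="rigflow.nodes.basic:table_sink",
            params={"path": str(table_path)},
        ),
    ]
    edges = [
        edge("KeyPress##0", "Key", "Trial Generator##0", "Start/Previous Trial Result"),
        edge("Trial Generator##0", "Trial Definition", "Trial Controller##0", "Trial Definition"),
        edge("Trial Controller##0", "Trial Result", "Save Pandas DF##0", "Row"),
        edge("Trial Controller##0", "Trial History", "Trial Generator##0", "Start/Previous Trial Result"),
    ]
    return make_graph_text(nodes, edges)


@pytest.fixture
def fast_config(tmp_path):
    """Engine config with short grace periods for quick test runs."""
    return EngineConfig(
        run_seed=1,
        log_dir=str(tmp_path / "run"),
        heartbeat_period_s=0.2,
        missed_heartbeats=25,
        pol_timeout_s=30.0,
        stop_grace_s=8.0,
    )
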