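"""Runtime engine: process topology, delivery semantics, lifecycle.

These tests start real process trees, so they use short runs and generous
shutdown grace.  Exact drop *counts* are asserted only where the timing is
controlled by construction; otherwise the conservation and ordering
invariants are asserted, which hold for any interleaving.
"""

import json
import os
import time

import pandas as pd
import pytest

import rigflow as rf
from rigflow.engine import EngineConfig, EngineStartError, start_graph

from conftest import chain_graph, edge, make_graph_text, node


def run_for(graph, config, seconds):
    handle = start_graph(graph, config)
    time.sleep(seconds)
    return handle.stop()


def assert_all_dead(pids):
    for pid in pids:
        try:
            os.kill(pid, 0)
        except ProcessLookupError:
            continue
        raise AssertionError(f"pid {pid} survived the stop")


class TestTopology:
    @pytest.mark.parametrize("n_transforms", [1, 3])
    def test_census_is_2n_plus_4(self, n_transforms, fast_config):
        """N nodes run as exactly 2N+4 processes: director + 3 forwarders +
        a com/worker pair per node."""
        g = chain_graph(n_transforms=n_transforms)
        n = len(g.nodes)
        handle = start_graph(g, fast_config)
        try:
            assert handle.process_census() == 2 * n + 4
        finally:
            report = handle.stop()
        assert report.orphan_count == 0

    def test_single_unconnected_source_runs_as_six_processes(self, fast_config):
        g = rf.parse_graph(
            make_graph_text(
                [
                    node(
                        "Lonely",
                        "source",
                        outputs=["Out"],
                        worker_ref="rigflow.nodes.basic:scripted_source",
                        params={"schedule": [1, 2, 3]},
                    )
                ],
                [],
            )
        )
        handle = start_graph(g, fast_config)
        try:
            assert handle.process_census() == 6
        finally:
            handle.stop()

    def test_census_on_stopped_handle_is_an_error(self, fast_config):
        g = chain_graph()
        handle = start_graph(g, fast_config)
        handle.stop()
        with pytest.raises(rf.EngineError):
            handle.process_census()


class TestStartFailure:
    def test_worker_raising_in_initialise_aborts_with_no_survivors(self, tmp_path):
        g = rf.parse_graph(
            make_graph_text(
                [
                    node(
                        "Bad",
                        "source",
                        outputs=["Out"],
                        worker_ref="tests.broken_workers:raises_on_init",
                    )
                ],
                [],
            )
        )
        # worker_ref resolution happens caller-side first; use a real module
        g.nodes[0].worker_ref = "broken_workers:raises_on_init"
        import sys

        sys.path.insert(0, str(_write_broken_module(tmp_path)))
        try:
            with pytest.raises(EngineStartError, match="initialise"):
                start_graph(g, EngineConfig(pol_timeout_s=20.0))
        finally:
            sys.path.pop(0)

    def test_unresolvable_worker_ref_fails_before_any_spawn(self):
        g = chain_graph()
        g.nodes[0].worker_ref = "no.such.module:factory"
        with pytest.raises(rf.NodeFault):
            start_graph(g, EngineConfig())

    def test_remote_placement_refused(self):
        g = chain_graph()
        g.nodes[0].placement = "lab-pc-2"
        with pytest.raises(EngineStartError, match="remote execution not implemented"):
            start_graph(g, EngineConfig())


def _write_broken_module(tmp_path):
    mod_dir = tmp_path / "mods"
    mod_dir.mkdir()
    (mod_dir / "broken_workers.py").write_text(
        "from rigflow.node_api import WorkerDefinition\n"
        "def raises_on_init(params):\n"
        "    def initialise(ctx):\n"
        "        raise RuntimeError('device not found')\n"
        "    return WorkerDefinition(work=lambda ctx: None, initialise=initialise)\n"
    )
    return mod_dir


class TestDeliverySemantics:
    def test_burst_into_sleeping_sink_drops_all_but_first(self, fast_config):
        """10 packets in a fast burst while the sink callback sleeps 2 s:
        the no-buffering rule forwards the first and discards the rest."""
        g = chain_graph(
            n_transforms=0,
            schedule=list(range(10)),
            interval_s=0.0,
            sink_ref="rigflow.nodes.basic:sleepy_sink",
        )
        g.nodes[-1].parameters.append(rf.ParameterSpec("sleep_s", 2.0))
        report = run_for(g, fast_config, 1.0)
        c = report.link_counters["Src##0:Out->Snk##0:In"]
        assert c["emitted"] == 10
        assert c["delivered"] + c["dropped"] == 10
        assert 1 <= c["delivered"] <= 2  # first delivered; at most one more post-wake
        assert c["dropped"] >= 8

    def test_conservation_holds_on_every_link(self, fast_config):
        report = run_for(chain_graph(n_transforms=2, schedule=list(range(40)), interval_s=0.002), fast_config, 1.0)
        assert report.link_counters
        assert report.conservation_ok()

    def test_delivered_ids_strictly_increase_no_reordering(self, fast_config, tmp_path):
        """Com logs show gapless local ids mapping to increasing upstream ids."""
        config = fast_config
        report = run_for(chain_graph(n_transforms=1, schedule=list(range(30))), config, 1.2)
        logs = sorted(os.listdir(config.log_dir))
        comlogs = [f for f in logs if f.endswith(".comlog.csv")]
        assert comlogs
        for f in comlogs:
            df = pd.read_csv(os.path.join(config.log_dir, f))
            if len(df) == 0:
                continue
            assert df["local_packet_id"].tolist() == list(range(len(df)))
            ups = df["upstream_packet_id"].tolist()
            assert ups == sorted(ups) and len(set(ups)) == len(ups)

    def test_substate_rows_match_delivered_packets(self, fast_config):
        g = chain_graph(n_transforms=0, schedule=list(range(25)), interval_s=0.004)
        report = run_for(g, fast_config, 1.2)
        c = report.link_counters["Src##0:Out->Snk##0:In"]
        sub = pd.read_csv(os.path.join(fast_config.log_dir, "Snk__0.substate.csv"))
        assert len(sub) == c["delivered"]


class TestParameters:
    def _param_graph(self, tmp_path):
        """Source streams; a udf-style transform scales by parameter 'gain'."""
        nodes = [
            node(
                "Src",
                "source",
                outputs=["Out"],
                worker_ref="rigflow.nodes.basic:scripted_source",
                params={"schedule": list(range(200)), "interval_s": 0.02},
            ),
            node(
                "Amp",
                "transform",
                inputs=["In"],
                outputs=["Out"],
                worker_ref="gain_worker:make_worker",
                params={"gain": 1},
            ),
            node("Snk", "sink", inputs=["In"], worker_ref="rigflow.nodes.basic:table_sink",
                 params={"path": str(tmp_path / "out.csv")}),
        ]
        edges = [edge("Src##0", "Out", "Amp##0", "In"), edge("Amp##0", "Out", "Snk##0", "In")]
        (tmp_path / "gain_worker.py").write_text(
            "from rigflow.node_api import WorkerDefinition\n"
            "def make_worker(params):\n"
            "    def work(ctx, ev):\n"
            "        return [{'value': int(ev.item[0]), 'gain': int(ctx.parameters['gain'])}]\n"
            "    return WorkerDefinition(work=work)\n"
        )
        return rf.parse_graph(make_graph_text(nodes, edges))

    def test_updatable_parameter_visible_at_a_later_pass(self, tmp_path, fast_config):
        import sys

        sys.path.insert(0, str(tmp_path))
        try:
            g = self._param_graph(tmp_path)
            handle = start_graph(g, fast_config)
            time.sleep(0.6)
            ok, msg = handle.update_parameter("Amp##0", "gain", 7)
            assert ok, msg
            time.sleep(0.8)
            handle.stop()
        finally:
            sys.path.pop(0)
        df = pd.read_csv(tmp_path / "out.csv")
        assert set(df["gain"]) == {1, 7}  # old value early, new value later
        # the switch is clean: gain never flaps back
        switch = df["gain"].ne(1).idxmax()
        assert (df["gain"].iloc[switch:] == 7).all()

    def test_non_updatable_parameter_refused(self, fast_config):
        g = chain_graph()
        g.nodes[0].parameters.append(rf.ParameterSpec("interval_locked", 1, updatable=False))
        handle = start_graph(g, fast_config)
        try:
            ok, msg = handle.update_parameter("Src##0", "interval_locked", 2)
            assert not ok and "refused" in msg
        finally:
            handle.stop()

    def test_unknown_parameter_and_node_error_acks(self, fast_config):
        handle = start_graph(chain_graph(), fast_config)
        try:
            ok1, msg1 = handle.update_parameter("Src##0", "nope", 1)
            ok2, msg2 = handle.update_parameter("Ghost##9", "x", 1)
            assert not ok1 and "unknown parameter" in msg1
            assert not ok2 and "unknown node" in msg2
            assert handle.process_census() == 2 * len(handle.graph.nodes) + 4  # run unaffected
        finally:
            handle.stop()


class TestLifecycle:
    def test_stop_idle_graph_all_end_of_life_ran_no_orphans(self, fast_config):
        handle = start_graph(chain_graph(schedule=[1]), fast_config)
        pids = handle.pids()
        report = handle.stop()
        assert report.orphan_count == 0
        assert report.end_of_life_all
        assert all(s["end_of_life"] for s in report.node_status.values())
        assert_all_dead(pids)

    def test_stop_mid_emission_conserves_counters(self, fast_config):
        g = chain_graph(n_transforms=1, schedule=list(range(10_000)), interval_s=0.0)
        handle = start_graph(g, fast_config)
        time.sleep(0.5)
        pids = handle.pids()
        report = handle.stop()  # source is mid-stream
        assert report.conservation_ok()
        assert report.orphan_count == 0
        assert_all_dead(pids)

    def test_worker_ignoring_stop_is_force_killed_without_orphans(self, tmp_path):
        import sys

        (tmp_path / "stubborn_worker.py").write_text(
            "import time\n"
            "from rigflow.node_api import WorkerDefinition\n"
            "def make_worker(params):\n"
            "    def work(ctx):\n"
            "        time.sleep(3600)\n"  # never yields to the stop signal
            "    return WorkerDefinition(work=work)\n"
        )
        g = rf.parse_graph(
            make_graph_text(
                [node("Stuck", "source", outputs=["Out"], worker_ref="stubborn_worker:make_worker")],
                [],
            )
        )
        sys.path.insert(0, str(tmp_path))
        try:
            handle = start_graph(g, EngineConfig(stop_grace_s=1.5))
            time.sleep(0.3)
            pids = handle.pids()
            report = handle.stop()
        finally:
            sys.path.pop(0)
        assert report.orphan_count == 0
        assert report.node_status["Stuck##0"]["end_of_life"] is False  # forced kill path
        assert_all_dead(pids)

    def test_faulting_source_does_not_take_down_the_graph(self, tmp_path, fast_config):
        import sys

        (tmp_path / "faulty_worker.py").write_text(
            "from rigflow.node_api import WorkerDefinition\n"
            "def make_worker(params):\n"
            "    def work(ctx):\n"
            "        raise ValueError('sensor glitch')\n"
            "    return WorkerDefinition(work=work)\n"
        )
        g = chain_graph(schedule=list(range(5)))
        g.nodes.insert(
            1,
            rf.NodeSpec(
                "Faulty", 0, "source",
                outputs=[rf.PortSpec("Out", "output")],
                worker_ref="faulty_worker:make_worker",
            ),
        )
        sys.path.insert(0, str(tmp_path))
        try:
            handle = start_graph(g, fast_config)
            time.sleep(0.8)
            assert handle.process_census() == 2 * len(g.nodes) + 4  # fault is contained
            report = handle.stop()
        finally:
            sys.path.pop(0)
        assert report.orphan_count == 0
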