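# cigpath

Context-specific views of BPMN-encoded clinical practice guidelines:
pruning, temporal-role inference and linearization.

## The problem

Computer-interpretable guidelines (CIGs) encode a clinical pathway as a
process model — tasks, decisions and flows.  Decision-support systems built
on them usually show the clinician either the whole static pathway
(information overload) or only the single next recommendation (no
orientation).  `cigpath` computes the middle ground: given the guideline
model and the current treatment context of one patient, it derives a
*contextualized guideline* — a short, ordered task list in which

* parts of the pathway that are provably unreachable under the recorded
  data are **pruned**,
* every remaining task carries a **temporal role**: `past` (already done,
  cannot recur), `present` (a choice that can be taken right now) or
  `future` (possibly relevant later — including already-executed tasks that
  sit on a live cycle and may recur), and
* the surviving graph is **linearized** into a single topologically sorted
  list that keeps related tasks next to each other.

Processing is stateless and deterministic: every request recomputes the
result from the full model and the full patient history, so a context
change can never leave stale state behind, and identical inputs always
produce byte-identical output.

## The model

The guideline procedures layer is a restricted BPMN 2.0 process: one start
event, end events, tasks, exclusive (XOR) and parallel (AND) gateways, and
sequence flows optionally guarded by a condition over context variables
(e.g. `A == true`, `crp < 50`).  The treatment context is a JSON document
listing executed tasks with their recorded scalar outcomes plus named
variables; an executed task's outcome is visible to conditions under the
task's id.

Conditions are evaluated in Kleene's strong three-valued logic: a guard is
satisfied, unsatisfied, or *cannot be decided yet* (`UNKNOWN`, when it
references data not yet recorded).  Reachability is the least fixpoint of

```
reach(start) = TRUE
avail(u→v)   = reach(u) ∧ cond(u→v)          (Kleene ∧)
reach(v)     = ⋀ avail(e)  over incoming e   for a parallel join
             = ⋁ avail(e)  over incoming e   otherwise
```

A vertex with `reach = FALSE` is unreachable under *every* completion of
the unknown data and is pruned.  A separate two-valued "confirmed facts"
token game determines what is enabled now (only decidedly-true guards pass
control; executed tasks pass it on, recorded history is trusted), which
yields `present`; an executed task is `past` exactly when no surviving
cycle can bring it back.  Linearization removes, per remaining cycle, the
edge farthest from the start (by BFS distance) and runs a modified Kahn
sort that prefers successors of the last emitted vertex.

## Worked example

The synchronization pattern — parallel tasks A and B whose flows converge
on a join guarded by `A == true` and `B == true`, followed by task C — is
bundled as a fixture together with its nine exhaustive contexts:

```
$ cigpath patterns synchronization --out fixtures
$ cigpath contextualize --model fixtures/synchronization.bpmn --context fixtures/Pat02.json
{
  "entries": [
    {"taskId": "A", "label": "Task A", "role": "past"},
    {"taskId": "B", "label": "Task B", "role": "present"},
    {"taskId": "C", "label": "Task C", "role": "future"}
  ],
  "pruned": [],
  "removedEdges": [],
  "diagnostics": []
}
```

Context `Pat02` records A executed with outcome `true` and nothing about B:
so A is done (`past`), B is the currently available step (`present`), and C
may follow once B succeeds (`future`).  Had B been recorded with outcome
`false` (context `Pat03`), the join could never fire and C would appear
under `"pruned"` instead.

The same pipeline is available as a library
(`cigpath.contextualize_model(model, ctx)`) and as a stateless HTTP facade
(`cigpath serve`; `POST /guidelines`, then
`POST /guidelines/{id}/contextualize`).

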