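# Model file formats

## Native JSON (schema version 1)

The native serialization keeps pathway overlap explicit. Top-level keys:

```json
{
 "schema_version": 1,
 "pathways": [
  {"id": "pw00", "name": "Glycolysis", "class": "metabolic"}
 ],
 "components": [
  {"id": "HK1", "name": "HK1", "kind": "gene", "pathways": ["pw00"]}
 ],
 "reactions": [
  {
   "id": "r0001",
   "reactants": [{"component": "HK1", "role": 1.0}],
   "products": [{"component": "g6p", "role": 1.0}],
   "law": {"type": "mass_action", "k": 1.0},
   "pathways": ["pw00"]
  }
 ]
}
```

- `kind` ∈ {`gene`, `protein`, `compound`, `other`}; only `gene` components
  receive initial values from an expression profile.
- `pathways` on a component must be non-empty; every referenced pathway id
  must be declared under the top-level `pathways` key.
- `role` is a positive real: exponent on reactants, linear weight on products
  (default 1.0 when omitted).
- `law.type` ∈ {`mass_action`, `unit`}; `unit` ignores `k` (treats it as 1).
- `class` on a pathway is an optional label (e.g. `metabolic` / `signaling`);
  it is carried through to drug impact summaries but does not affect the
  computation.

`load_model(path)` validates all referential invariants and raises a
`ModelValidationError` listing every violation; `validate_model(model)`
returns the violation list without raising.

## SBML Level 3 import

`load_model(path, format="sbml")` (or any `.xml`/`.sbml` extension) maps:

- species → components; reactions → reactions with stoichiometry → `role`;
- a kinetic-law local parameter named `k` → the mass-action rate constant;
- Groups-package groups → pathways (members may be species or reactions);
  alternatively a species notes line `pathways: a;b` declares memberships;
- a species notes line `kind: gene` (or protein/compound/other) sets the
  component kind; unannotated species default to `other`.

Species without any pathway membership fail validation, mirroring the native
format's invariant. Export is JSON-only.
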