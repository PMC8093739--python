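"""Simulate a tagged-manta deployment, then screen and segment detections.

Generates 7 days of synthetic instrument and detection data with known
truth, removes suspected false detections with the interval-ratio screen,
and segments the kept detections into resident events.
"""

from tidaltag import synthetic_data as sd, telemetry as tm

bundle = sd.make_fixture(seed=42, size="small")
led = bundle.ledger()
print(f"simulated {led['n_bins']} five-minute bins, "
      f"prevalence {led['prevalence']:.3f}, {led['n_pings']} pings")

kept, flagged = tm.filter_false_detections(bundle.detections)
print(f"kept {len(kept)} detections, flagged {len(flagged)} suspected false "
      "(isolated pings in streams with more long than short intervals)")

events = tm.detect_resident_events(kept)
frame = tm.events_to_frame(events)
print(f"{len(events)} resident events; mean duration "
      f"{frame['duration_min'].mean():.1f} min, "
      f"longest {frame['duration_min'].max():.0f} min")
print(frame.head().to_string(index=False))
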