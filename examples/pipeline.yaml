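# End-to-end demo: simulate a 20-bait dataset, adjust, fine-map.
# Run with:  chicfine run --config examples/pipeline.yaml --out-dir demo_run/
seed: 5
n_bins: 10
n_retained: 1000
thin: 100
simulate:
  n_fragments: 8000
  n_chromosomes: 2
  n_baits: 20
  window_bp: 600000
  n_contacts_range: [1, 3]
  seed: 5
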