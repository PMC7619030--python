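{
  "english": {"north": "north", "south": "south", "east": "east", "west": "west"},
  "german": {"north": "norden", "south": "süden", "east": "osten", "west": "westen"},
  "spanish": {"north": "norte", "south": "sur", "east": "este", "west": "oeste"},
  "italian": {"north": "nord", "south": "sud", "east": "est", "west": "ovest"},
  "french": {"north": "nord", "south": "sud", "east": "est", "west": "ouest"}
}
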