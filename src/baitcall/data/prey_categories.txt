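UNCHARACTERIZED/ORPHAN PROTEINS
TRANSCRIPTION CONTROL PROTEINS
RNA PROCESSING PROTEINS
RIBOSOMAL & TRANSLATION PROTEINS
METABOLIC & TRANSPORT PROTEINS
CELL ENVELOPE PROTEINS
DNA ARCHITECTURE/STRUCTURE PROTEINS
DNA REPLICATION PROTEINS
CHROMOSOME SEGREGATION & CELL DIVISION PROTEINS
STRESS & STARVATION RESPONSE PROTEINS
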