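# All annotations that are (transitively) based on a given annotation,
# here the resource annotation ex:ra7. The basedOn relation is declared
# transitive; the one-or-more-step property path computes its closure.
PREFIX kiao: <http://kabob.ucdenver.edu/iao/>
PREFIX iao: <http://purl.obolibrary.org/obo/iao/>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX ex: <http://example.org/>

SELECT DISTINCT ?annotation
WHERE {
  ?annotation kiao:basedOn+ ex:ra7 .
  { ?annotation rdf:type kiao:RdfResourceAnnotation . }
  UNION
  { ?annotation rdf:type kiao:RdfGraphAnnotation . }
}
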