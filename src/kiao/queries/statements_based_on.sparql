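# All reified statements having at least one statement element that is
# (transitively) based on a given annotation, here ex:ra7. The element
# links (each a subproperty of obo:has_part) step from statement to
# element; basedOn+ closes the provenance chain, which may pass through
# other statement elements.
PREFIX kiao: <http://kabob.ucdenver.edu/iao/>
PREFIX iao: <http://purl.obolibrary.org/obo/iao/>
PREFIX obo: <http://purl.obolibrary.org/obo/>
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX ex: <http://example.org/>

SELECT DISTINCT ?statement
WHERE {
  ?statement (kiao:subjectElement|kiao:propertyElement|kiao:objectElement) ?element .
  ?element kiao:basedOn+ ex:ra7 .
}
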