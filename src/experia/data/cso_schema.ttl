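# Clinical Sentiment Ontology schema: three connected vocabularies.
#   ogms:  clinical-medicine concepts (disease, diagnosis, procedure),
#          modelled after the Ontology for General Medical Science
#   marl:  opinion/sentiment annotation concepts, modelled after the
#          published Marl opinion ontology
#   cso:   the application layer linking analysed clinical experience
#          to the expressed opinions
# Properties marked "artifact extension" are not part of the connected
# class diagram the vocabularies come from; they carry the case fields
# (identifier, decision, VAS preference attributes, text provenance)
# that the experience-inference engine needs.

@prefix rdf:  <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix owl:  <http://www.w3.org/2002/07/owl#> .
@prefix ogms: <http://example.org/experia/ogms#> .
@prefix marl: <http://www.gsi.upm.es/ontologies/marl/ns#> .
@prefix cso:  <http://example.org/experia/cso#> .

# --- clinical-medicine concepts ------------------------------------------

ogms:Disease a owl:Class ; rdfs:label "disease" .
ogms:Diagnosis a owl:Class ; rdfs:label "diagnosis" .
ogms:TherapeuticProcedure a owl:Class ; rdfs:label "therapeutic procedure" .

cso:Problem a owl:Class .
cso:Complication a owl:Class .
cso:Therapy a owl:Class .

# --- opinion / sentiment concepts ----------------------------------------

marl:SentimentAnalysis a owl:Class .
marl:Opinion a owl:Class .
marl:SourceText a owl:Class .
marl:DescribedObject a owl:Class .
marl:DescribedObjectFeature a owl:Class .

# --- application layer ----------------------------------------------------

cso:AnalysisResult a owl:Class .
cso:AnalyzedExperience a owl:Class .
cso:AnalyzedExperienceAspect a owl:Class .
cso:ClinicalConditionSet a owl:Class ; rdfs:subClassOf cso:AnalysisResult .
cso:ClinicalOpinionSet a owl:Class ; rdfs:subClassOf cso:AnalysisResult .

# --- object / datatype properties -----------------------------------------

cso:hasConditions a rdf:Property ;
    rdfs:domain cso:AnalyzedExperience ; rdfs:range cso:ClinicalConditionSet .
cso:hasOpinionSet a rdf:Property ;
    rdfs:domain cso:AnalyzedExperience ; rdfs:range cso:ClinicalOpinionSet .
cso:hasCondition a rdf:Property ; rdfs:domain cso:ClinicalConditionSet .
cso:hasProcedure a rdf:Property ; rdfs:domain cso:AnalyzedExperience .
marl:hasPolarity a rdf:Property .
marl:describesObject a rdf:Property ;
    rdfs:domain marl:Opinion ; rdfs:range marl:DescribedObject .
marl:hasOpinion a rdf:Property ; rdfs:range marl:Opinion .

# artifact extensions (case bookkeeping for the inference engine)
cso:hasCaseId a rdf:Property ; rdfs:domain cso:AnalyzedExperience .
cso:hasDecision a rdf:Property ; rdfs:domain cso:AnalyzedExperience .
cso:hasPreferenceAttribute a rdf:Property ;
    rdfs:domain cso:AnalyzedExperience ; rdfs:range cso:AnalyzedExperienceAspect .
cso:hasAttributeName a rdf:Property ; rdfs:domain cso:AnalyzedExperienceAspect .
cso:hasVasValue a rdf:Property ; rdfs:domain cso:AnalyzedExperienceAspect .
cso:hasPriorityRank a rdf:Property ; rdfs:domain cso:AnalyzedExperienceAspect .
cso:hasOpinionWord a rdf:Property ; rdfs:domain marl:Opinion .
cso:fromDocument a rdf:Property ; rdfs:domain marl:Opinion .
cso:atSentenceIndex a rdf:Property ; rdfs:domain marl:Opinion .
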